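"""Codon volatility under a genetic code, and the class-level comparison.

The volatility of a sense codon is the proportion of its single-nucleotide
point-mutation neighbors that encode a different amino acid; neighbors that
are stop codons are excluded from the denominator by default (the
convention of the index as originally proposed). A gene's volatility is
the unweighted mean over its sense codons, and functional classes of genes
(housekeeping vs putatively secreted) are compared with a two-sided Welch
t-test on per-gene values.

Under the standard code every sense codon has 9 neighbors, 0-2 of which
are stops, so denominators are 7, 8 or 9, and v = 1.0 exactly for the two
single-codon residues ATG (Met) and TGG (Trp).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

__all__ = [
    "GeneticCode",
    "codon_volatility",
    "volatility_table",
    "GeneVolatility",
    "gene_volatility",
    "VolatilitySummary",
    "compare_class_volatility",
    "welch_t",
]


@dataclass(frozen=True)
class GeneticCode:
    """A codon->residue map plus stop set (64 codons total)."""

    forward: dict  # sense codon -> one-letter residue
    stops: frozenset
    name: str = "standard"

    def __post_init__(self):
        if len(self.forward) + len(self.stops) != 64:
            raise ValueError("genetic code must cover exactly 64 codons")

    @classmethod
    def standard(cls) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[1]
        return cls(forward=dict(t.forward_table),
                   stops=frozenset(t.stop_codons))

    def translate_codon(self, codon: str) -> str:
        codon = codon.upper()
        if codon in self.stops:
            return "*"
        return self.forward.get(codon, "X")


_STANDARD = None


def standard_code() -> GeneticCode:
    global _STANDARD
    if _STANDARD is None:
        _STANDARD = GeneticCode.standard()
    return _STANDARD


def codon_volatility(codon: str, code: GeneticCode | None = None,
                     count_stop_neighbors: bool = False) -> Fraction:
    """Volatility of one sense codon as an exact Fraction.

    Enumerates the 9 single-nucleotide neighbors; with the default
    ``count_stop_neighbors=False`` stop neighbors are dropped from the
    denominator (they always count as non-synonymous when included).
    Raises ValueError for stop codons ("volatility undefined for stops")
    and for non-ACGT input.
    """
    code = code or standard_code()
    codon = codon.upper()
    if len(codon) != 3 or any(c not in NUCLEOTIDES for c in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if codon in code.stops:
        raise ValueError(f"volatility undefined for stop codon {codon}")
    aa = code.forward[codon]
    num = den = 0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            nb = codon[:pos] + nt + codon[pos + 1:]
            if nb in code.stops:
                if count_stop_neighbors:
                    den += 1
                    num += 1
                continue
            den += 1
            if code.forward[nb] != aa:
                num += 1
    return Fraction(num, den)


def volatility_table(code: GeneticCode | None = None,
                     count_stop_neighbors: bool = False) -> dict[str, Fraction]:
    """v(c) for all 61 sense codons (exact rational values)."""
    code = code or standard_code()
    return {c: codon_volatility(c, code, count_stop_neighbors)
            for c in sorted(code.forward)}


@dataclass
class GeneVolatility:
    """Per-gene volatility with QC counts of skipped material."""

    value: float
    n_codons_used: int
    n_stop_skipped: int = 0
    n_ambiguous_skipped: int = 0
    trimmed_nt: int = 0


def gene_volatility(cds: str, code: GeneticCode | None = None,
                    count_stop_neighbors: bool = False) -> GeneVolatility:
    """Mean volatility over the sense codons of a coding sequence.

    A trailing partial codon is trimmed; stop codons and codons containing
    N (or other ambiguity) are skipped and counted in the QC fields.
    Raises ValueError if no usable codon remains.
    """
    code = code or standard_code()
    cds = cds.upper()
    trimmed = len(cds) % 3
    if trimmed:
        cds = cds[:len(cds) - trimmed]
    values = []
    n_stop = n_amb = 0
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        if any(c not in NUCLEOTIDES for c in codon):
            n_amb += 1
            continue
        if codon in code.stops:
            n_stop += 1
            continue
        values.append(float(codon_volatility(codon, code, count_stop_neighbors)))
    if not values:
        raise ValueError("no usable sense codon in coding sequence")
    return GeneVolatility(value=float(np.mean(values)),
                          n_codons_used=len(values),
                          n_stop_skipped=n_stop,
                          n_ambiguous_skipped=n_amb,
                          trimmed_nt=trimmed)


@dataclass
class VolatilitySummary:
    """Per-class mean/SE of gene volatilities with a Welch t comparison."""

    classes: tuple[str, str]
    mean: dict
    se: dict
    n: dict
    t: float
    p: float
    df: float


def welch_t(x, y, eps: float = 1e-12) -> tuple[float, float, float]:
    """Two-sided Welch t-test; SE denominator floored at eps.

    The floor keeps degenerate zero-variance classes finite: identical
    means give t = 0, P = 1; distinct means give a huge |t| and a P that
    underflows toward (but is reported as) a tiny positive number.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    diff = x.mean() - y.mean()
    if se2 <= eps ** 2:
        if diff == 0:
            return 0.0, 1.0, float(n1 + n2 - 2)
        se2 = eps ** 2
    t = diff / np.sqrt(se2)
    if v1 == 0 and v2 == 0:
        df = float(n1 + n2 - 2)
    else:
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    return float(t), p, float(df)


def compare_class_volatility(values_by_class: dict,
                             ) -> VolatilitySummary:
    """Compare per-gene volatilities between exactly two classes.

    ``values_by_class`` maps class label (e.g. "H", "S") to a sequence of
    per-gene volatility values; each class needs >= 2 genes. SE is the
    sample SD over genes divided by sqrt(n).
    """
    if len(values_by_class) != 2:
        raise ValueError("exactly two classes required")
    (la, xa), (lb, xb) = sorted(values_by_class.items())
    xa = np.asarray(xa, float)
    xb = np.asarray(xb, float)
    for lab, v in ((la, xa), (lb, xb)):
        if len(v) < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 genes")
    t, p, df = welch_t(xa, xb)
    return VolatilitySummary(
        classes=(la, lb),
        mean={la: float(xa.mean()), lb: float(xb.mean())},
        se={la: float(xa.std(ddof=1) / np.sqrt(len(xa))),
            lb: float(xb.std(ddof=1) / np.sqrt(len(xb)))},
        n={la: len(xa), lb: len(xb)},
        t=t, p=p, df=df)
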