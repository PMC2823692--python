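"""Cross-species protein identity: alignment, filtering, class comparison.

The divergence pipeline mirrors a blastp-based orthology comparison
between a query secretome/housekeeping set and a reference proteome:
local (Smith-Waterman style) affine-gap alignment under BLOSUM62 with
blastp's default gap penalties, a minimum-alignment-length filter, an
allele/duplicate dedup rule (drop the shorter of any pair at >= 80%
similarity), per-class mean percent identity, and a two-sided
Mann-Whitney rank-sum comparison of the per-protein identities.

Alignment itself is delegated to Bio.Align.PairwiseAligner; "similarity"
is blast-style positives (aligned pairs with a positive substitution
score). X scores 0 against everything and never counts as an identity.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "IdentityPipelineParams",
    "ClassComparison",
    "MannWhitneyResult",
    "align_proteins",
    "dedup_alleles",
    "class_identity",
    "mann_whitney",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix and affine gap penalties.

    Defaults mirror blastp: BLOSUM62, gap open -11, gap extend -1 (a gap
    of length k costs 11 + (k-1)). The matrix is made X-neutral: any pair
    involving X scores 0.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0

    def __post_init__(self):
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")

    @functools.cached_property
    def matrix(self):
        m = substitution_matrices.load(self.matrix_name).copy()
        alpha = m.alphabet
        if "X" in alpha:
            for c in alpha:
                m["X", c] = 0.0
                m[c, "X"] = 0.0
        return m

    def aligner(self, mode: str) -> Align.PairwiseAligner:
        if mode not in ("local", "global"):
            raise ValueError(f"unknown alignment mode {mode!r}")
        a = Align.PairwiseAligner()
        a.mode = mode
        a.substitution_matrix = self.matrix
        a.open_gap_score = self.gap_open
        a.extend_gap_score = self.gap_extend
        return a

    def pair_score(self, x: str, y: str) -> float:
        return float(self.matrix[x, y])


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class AlignmentResult:
    """Column statistics of one pairwise alignment."""

    aligned_a: str
    aligned_b: str
    score: float
    columns: int
    identities: int
    similarities: int

    @property
    def percent_identity(self) -> float:
        return self.identities / self.columns

    @property
    def percent_similarity(self) -> float:
        return self.similarities / self.columns


@dataclass(frozen=True)
class IdentityPipelineParams:
    min_alignment_length: int = 100
    dedup_similarity: float = 0.80

    def __post_init__(self):
        if self.min_alignment_length < 1:
            raise ValueError("min_alignment_length must be >= 1")
        if not 0 < self.dedup_similarity <= 1:
            raise ValueError("dedup_similarity must be in (0, 1]")


def _seq_of(x) -> str:
    return x if isinstance(x, str) else x.seq


def align_proteins(a, b, scheme: ScoringScheme = DEFAULT_SCHEME,
                   mode: str = "local") -> AlignmentResult:
    """Optimal pairwise alignment with column statistics.

    ``a``/``b`` may be strings or SequenceRecords. Identities are columns
    with equal non-X residues; similarities are columns whose pair scores
    positively under the scheme (so identities <= similarities <= columns).
    """
    sa, sb = _seq_of(a).upper(), _seq_of(b).upper()
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    aligner = scheme.aligner(mode)
    aln = aligner.align(sa, sb)
    try:
        best = aln[0]
    except IndexError:
        raise ValueError("no non-empty optimal alignment (all scores <= 0 "
                         "in local mode)") from None
    aligned_a, aligned_b = str(best[0]), str(best[1])
    columns = identities = similarities = 0
    for x, y in zip(aligned_a, aligned_b):
        columns += 1
        if x == "-" or y == "-":
            continue
        if scheme.pair_score(x, y) > 0:
            similarities += 1
        if x == y and x != "X":
            identities += 1
    if columns == 0:
        raise ValueError("empty alignment")
    return AlignmentResult(aligned_a=aligned_a, aligned_b=aligned_b,
                           score=float(best.score), columns=columns,
                           identities=identities, similarities=similarities)


def dedup_alleles(records, scheme: ScoringScheme = DEFAULT_SCHEME,
                  params: IdentityPipelineParams = IdentityPipelineParams()):
    """Remove putative alleles/close duplicates within one set.

    Records are visited in descending-length order (length ties broken by
    id, and the lexicographically larger id is the one dropped); a record
    is discarded when its blast-style positives against any longer retained
    record, normalized by the shorter sequence's length, reach
    ``params.dedup_similarity``. Normalizing by the shorter sequence rather
    than by aligned columns keeps a short spurious local alignment between
    unrelated proteins from counting as high similarity. The result is
    independent of input order.
    """
    recs = list(records)
    if not recs:
        raise ValueError("empty record set")
    order = sorted(recs, key=lambda r: (-len(r.seq), r.id))
    kept = []
    for rec in order:
        drop = False
        for other in kept:
            try:
                res = align_proteins(rec, other, scheme, mode="local")
            except ValueError:
                continue  # nothing aligns: clearly dissimilar
            sim = res.similarities / min(len(rec.seq), len(other.seq))
            if sim >= params.dedup_similarity:
                drop = True
                break
        if not drop:
            kept.append(rec)
    # restore input order
    kept_ids = {r.id for r in kept}
    return [r for r in recs if r.id in kept_ids]


@dataclass
class MannWhitneyResult:
    u: float
    p: float
    method: str  # "exact" | "asymptotic"
    degenerate: bool = False


def mann_whitney(sample1, sample2) -> MannWhitneyResult:
    """Two-sided Mann-Whitney rank-sum test.

    U is the statistic of ``sample1`` (number of pairs where sample1 wins,
    ties counted half). P is exact by enumeration when n1+n2 <= 12 and
    there are no ties, otherwise a normal approximation with tie and
    continuity corrections. If every value in both samples is identical
    the comparison is degenerate: U = n1*n2/2, P = 1.
    """
    x = np.asarray(sample1, float)
    y = np.asarray(sample2, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(u=len(x) * len(y) / 2.0, p=1.0,
                                 method="degenerate", degenerate=True)
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue),
                             method=method)


@dataclass
class ClassComparison:
    """Per-class identity summaries and the rank-sum comparison."""

    mean_identity: dict
    n: dict
    u: float
    p: float


def class_identity(queries, labels: dict, reference,
                   scheme: ScoringScheme = DEFAULT_SCHEME,
                   params: IdentityPipelineParams = IdentityPipelineParams(),
                   ) -> tuple[pd.DataFrame, ClassComparison]:
    """Best-hit identity of each query against a reference proteome.

    For each query the best hit is the highest-scoring local alignment
    (ties broken by reference id); queries whose best alignment spans
    fewer than ``params.min_alignment_length`` columns are excluded from
    the class means. ``labels`` maps query id to its class (e.g. "H"/"S").
    Returns a per-query table and, when exactly two classes survive, the
    Mann-Whitney comparison of their identity samples.

    Raises ValueError if the reference is empty or a class ends up with no
    surviving query.
    """
    reference = list(reference)
    if not reference:
        raise ValueError("reference proteome is empty")
    aligner = scheme.aligner("local")
    rows = []
    for q in queries:
        best_score, best_ref = -np.inf, None
        for ref in reference:
            s = aligner.score(q.seq, ref.seq)
            if s > best_score or (s == best_score and best_ref is not None
                                  and ref.id < best_ref.id):
                best_score, best_ref = s, ref
        res = align_proteins(q, best_ref, scheme, mode="local")
        kept = res.columns >= params.min_alignment_length
        rows.append({
            "query": q.id,
            "class": labels.get(q.id, "U"),
            "best_hit": best_ref.id,
            "score": res.score,
            "aligned_columns": res.columns,
            "percent_identity": res.percent_identity,
            "percent_similarity": res.percent_similarity,
            "kept": kept,
        })
    table = pd.DataFrame(rows)
    kept = table[table["kept"]]
    by_class = {c: g["percent_identity"].to_numpy()
                for c, g in kept.groupby("class")}
    for c in sorted(set(labels.values())):
        if c not in by_class or len(by_class[c]) == 0:
            raise ValueError(
                f"class {c!r} has no query surviving the "
                f">= {params.min_alignment_length} aa alignment filter")
    if len(by_class) == 2:
        (ca, va), (cb, vb) = sorted(by_class.items())
        mw = mann_whitney(va, vb)
        comparison = ClassComparison(
            mean_identity={c: float(v.mean()) for c, v in by_class.items()},
            n={c: len(v) for c, v in by_class.items()},
            u=mw.u, p=mw.p)
    else:
        comparison = ClassComparison(
            mean_identity={c: float(v.mean()) for c, v in by_class.items()},
            n={c: len(v) for c, v in by_class.items()},
            u=float("nan"), p=float("nan"))
    return table, comparison
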