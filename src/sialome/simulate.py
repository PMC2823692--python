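"""Synthetic data with the statistical structure the pipeline assumes.

Generators for: an EST library drawn from a transcript pool with a
Zipf-like (power-law) abundance spectrum, so few dominant families and
many singletons; paired ortholog proteins at configurable divergence
regimes (the study's two regimes being ~70% and ~91% identity); coding
sequences drawn from a codon-usage vector with a known expected mean
volatility; and small paralog protein families evolved down a random
binary tree for tree-building truth. All generators are pure functions of
their arguments plus an integer seed, and always return the ground truth
beside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import SequenceRecord
from .phylo import Clade
from .volatility import GeneticCode, standard_code, volatility_table

__all__ = [
    "SyntheticConfig",
    "simulate_transcriptome_and_reads",
    "tile_reads",
    "simulate_ortholog_pairs",
    "simulate_coding_genes",
    "codon_usage_for_mean_volatility",
    "simulate_protein_family",
]

NUCLEOTIDES = np.array(list("ACGT"))
AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SyntheticConfig:
    """Default study conditions for the synthetic library.

    The library emulates ~1,750 single-pass reads from a non-normalized
    salivary-gland cDNA pool: a skewed power-law abundance over ~900
    transcripts reproduces a singleton-heavy cluster spectrum; read
    lengths are Sanger-like (mean 550 nt, sd 100); the substitution error
    rate of 0.002/nt corresponds to trimmed high-quality Sanger sequence.
    """

    seed: int = 0
    n_transcripts: int = 900
    n_reads: int = 1753
    abundance_alpha: float = 1.0
    transcript_length_mean: int = 1200
    transcript_length_sd: int = 300
    read_length_mean: int = 550
    read_length_sd: int = 100
    error_rate: float = 0.002
    indel_rate: float = 0.0
    n_pairs_per_class: dict = field(default_factory=lambda: {"S": 50, "H": 169})
    target_identity: dict = field(default_factory=lambda: {"S": 0.70, "H": 0.91})
    identity_sd: float = 0.02
    ortholog_length: int = 300
    family_size: int = 6
    family_divergence: float = 0.2

    def __post_init__(self):
        for p in (self.error_rate, self.indel_rate, self.identity_sd):
            if not 0 <= p <= 1:
                raise ValueError("rates must be probabilities")
        if self.abundance_alpha <= 0:
            raise ValueError("abundance_alpha must be positive")


def _random_transcript(rng, length: int) -> str:
    """A transcript with a CDS core: ATG + random sense codons + stop."""
    code = standard_code()
    sense = sorted(code.forward)
    utr5 = rng.integers(10, 60)
    n_codons = max(1, (length - utr5 - 6) // 3 - 10)
    cds = "ATG" + "".join(rng.choice(sense, size=n_codons)) + "TAA"
    utr3 = max(0, length - utr5 - len(cds))
    flank = lambda n: "".join(rng.choice(NUCLEOTIDES, size=n))
    return flank(utr5) + cds + flank(utr3)


def simulate_transcriptome_and_reads(config: SyntheticConfig):
    """EST library simulation: (transcripts, reads, truth map).

    Transcript abundances follow p_i proportional to (i+1)^-alpha. Each
    read takes a uniform start, a normal length (truncated at the
    transcript end, min 50 nt) and i.i.d. substitution errors at the
    configured rate. The truth map gives read id -> source transcript id.
    """
    if config.n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    rng = np.random.default_rng(config.seed)
    transcripts = []
    for i in range(config.n_transcripts):
        L = int(max(200, rng.normal(config.transcript_length_mean,
                                    config.transcript_length_sd)))
        transcripts.append(SequenceRecord(
            id=f"TR{i:05d}", seq=_random_transcript(rng, L),
            alphabet="nucleotide"))
    ranks = np.arange(1, config.n_transcripts + 1, dtype=float)
    p = ranks ** (-config.abundance_alpha)
    p /= p.sum()
    reads, truth = [], {}
    for j in range(config.n_reads):
        ti = int(rng.choice(config.n_transcripts, p=p))
        tseq = transcripts[ti].seq
        rl = int(max(50, rng.normal(config.read_length_mean,
                                    config.read_length_sd)))
        start = int(rng.integers(0, max(1, len(tseq) - 50)))
        sub = tseq[start:start + rl]  # truncated at the transcript end
        seq = _mutate_nt(rng, sub, config.error_rate)
        rid = f"EST{j:05d}"
        reads.append(SequenceRecord(id=rid, seq=seq, alphabet="nucleotide"))
        truth[rid] = transcripts[ti].id
    return transcripts, reads, truth


def _mutate_nt(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def tile_reads(transcripts, read_length: int = 400, stride: int = 250):
    """Deterministic error-free reads tiling each transcript end to end.

    With ``stride < read_length - min_overlap`` consecutive reads of one
    transcript are guaranteed to overlap, so the true clustering equals
    the transcript-of-origin partition. Returns (reads, truth map).
    """
    reads, truth = [], {}
    n = 0
    for tr in transcripts:
        starts = list(range(0, max(1, len(tr.seq) - read_length + 1), stride))
        last_start = max(0, len(tr.seq) - read_length)
        if starts[-1] != last_start:
            starts.append(last_start)
        for s in starts:
            rid = f"TILE{n:05d}"
            reads.append(SequenceRecord(id=rid,
                                        seq=tr.seq[s:s + read_length],
                                        alphabet="nucleotide"))
            truth[rid] = tr.id
            n += 1
    return reads, truth


def simulate_ortholog_pairs(n: int, target_identity: float,
                            identity_sd: float, length: int, seed: int = 0):
    """Paired ortholog proteins at a target percent identity.

    Per pair the identity is drawn from a normal(target, sd) truncated to
    (0, 1]; protein B substitutes each site of random protein A
    independently with probability 1 - identity, uniformly over the 19
    alternative residues. Returns [(record_a, record_b, true_identity)]
    where true_identity is the exact fraction of unchanged sites.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        while True:
            ident = (target_identity if identity_sd == 0
                     else rng.normal(target_identity, identity_sd))
            if 0 < ident <= 1:
                break
        a = rng.choice(AMINO_ACIDS, size=length)
        b = a.copy()
        changed = rng.random(length) < (1.0 - ident)
        for j in np.nonzero(changed)[0]:
            alt = [aa for aa in AMINO_ACIDS if aa != a[j]]
            b[j] = alt[rng.integers(0, 19)]
        true_identity = 1.0 - changed.sum() / length
        out.append((
            SequenceRecord(id=f"A{i:04d}", seq="".join(a), alphabet="protein"),
            SequenceRecord(id=f"B{i:04d}", seq="".join(b), alphabet="protein"),
            float(true_identity)))
    return out


def simulate_coding_genes(n: int, codon_usage: dict, n_codons: int,
                          seed: int = 0, include_start: bool = False,
                          code: GeneticCode | None = None):
    """Coding sequences drawn i.i.d. from a sense-codon usage vector.

    ``codon_usage`` maps sense codons to frequencies summing to 1 (mass on
    stop codons is an error). Genes are ``n_codons`` usage draws plus a
    TAA stop; the expected gene volatility is then exactly the
    usage-weighted mean of the volatility table. ``include_start``
    prepends a fixed ATG (off by default so that expectation holds).
    """
    code = code or standard_code()
    if n <= 0 or n_codons < 1:
        raise ValueError("n and n_codons must be positive")
    bad = set(codon_usage) & set(code.stops)
    if any(codon_usage[c] > 0 for c in bad):
        raise ValueError("codon usage assigns mass to stop codons")
    codons = sorted(c for c, f in codon_usage.items() if f > 0)
    freqs = np.array([codon_usage[c] for c in codons], float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("codon usage must sum to 1")
    unknown = set(codons) - set(code.forward)
    if unknown:
        raise ValueError(f"unknown codon(s) in usage: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    genes = []
    prefix = "ATG" if include_start else ""
    for i in range(n):
        body = "".join(rng.choice(codons, size=n_codons, p=freqs))
        genes.append(SequenceRecord(id=f"G{i:04d}",
                                    seq=prefix + body + "TAA",
                                    alphabet="nucleotide"))
    return genes


def codon_usage_for_mean_volatility(target: float,
                                    code: GeneticCode | None = None,
                                    tol: float = 1e-10) -> dict:
    """A sense-codon usage whose expected mean volatility equals ``target``.

    The uniform usage over the 61 sense codons is exponentially tilted,
    u(c) proportional to exp(lambda * v(c)), and lambda solved by
    bisection. Targets must lie strictly between the minimum and maximum
    codon volatility of the code (0.5 and 1.0 under the standard code).
    """
    code = code or standard_code()
    table = volatility_table(code)
    codons = sorted(table)
    v = np.array([float(table[c]) for c in codons])
    if not v.min() < target < v.max():
        raise ValueError(
            f"target {target} outside the achievable range "
            f"({v.min():.4f}, {v.max():.4f})")

    def mean_at(lam: float) -> float:
        w = np.exp(lam * (v - v.mean()))  # centered for numerical stability
        w /= w.sum()
        return float(w @ v)

    lo, hi = -200.0, 200.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if mean_at(mid) < target:
            lo = mid
        else:
            hi = mid
    lam = (lo + hi) / 2.0
    w = np.exp(lam * (v - v.mean()))
    w /= w.sum()
    return dict(zip(codons, w))


def _random_topology(rng, labels: list[str]) -> Clade:
    """Random binary topology by sequential pair joining."""
    nodes = [Clade(name=l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(Clade(children=[a, b]))
    return nodes[0]


def simulate_protein_family(ancestor_length: int, family_size: int,
                            divergence: float, seed: int = 0):
    """A paralog family evolved down a random binary tree.

    Branch lengths are divergence * Uniform(0.5, 1.5) expected
    substitutions per site; per branch each site substitutes with
    probability 1 - exp(-bl) (Poisson, at least one hit), uniformly over
    the 19 alternatives. Returns (records, true tree as a Clade).
    """
    if family_size < 3:
        raise ValueError("family_size must be >= 3")
    if divergence < 0:
        raise ValueError("divergence must be non-negative")
    rng = np.random.default_rng(seed)
    labels = [f"P{i:02d}" for i in range(family_size)]
    tree = _random_topology(rng, labels)
    ancestor = rng.choice(AMINO_ACIDS, size=ancestor_length)
    records = []

    def evolve(node: Clade, seq: np.ndarray):
        for child in node.children:
            bl = float(divergence * rng.uniform(0.5, 1.5))
            child.branch_length = bl
            cs = seq.copy()
            if bl > 0:
                hit = rng.random(len(cs)) < (1.0 - math.exp(-bl))
                for i in np.nonzero(hit)[0]:
                    alt = [aa for aa in AMINO_ACIDS if aa != cs[i]]
                    cs[i] = alt[rng.integers(0, 19)]
            if child.is_leaf:
                records.append(SequenceRecord(id=child.name, seq="".join(cs),
                                              alphabet="protein"))
            else:
                evolve(child, cs)

    evolve(tree, ancestor)
    records.sort(key=lambda r: r.id)
    return records, tree
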