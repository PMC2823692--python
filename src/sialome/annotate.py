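"""ORF calling, secretion prediction, and H/S/U functional classification.

ESTs from a directional cDNA library are translated in three forward
frames; the reportable ORF starts at the first methionine within the
first 300 predicted residues and runs to the first stop (or sequence
end), the longest such candidate across frames winning. A putative
signal peptide is called by a simple hydrophobic h-region heuristic
(pluggable; an external predictor's yes/no column in the evidence table
overrides it). Each transcript is then classified Housekeeping (H),
Secreted (S) or Unknown (U) with a subcategory from a closed,
keyword-driven vocabulary shipped as an editable data file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd
from Bio.Seq import Seq

from .io import EvidenceRow, SequenceRecord

__all__ = [
    "OrfCall",
    "ClassLabel",
    "GeneRecord",
    "three_frame_translate",
    "select_orf",
    "predict_secretion",
    "classify",
    "category_table",
    "load_vocabulary",
    "annotate_records",
]

ORF_SEARCH_WINDOW = 300  # residues searched for the initiator Met

HYDROPHOBIC = frozenset("AILFVMWC")  # h-region residues
SMALL = frozenset("AGSCT")           # cleavage-like small residues
AA_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class OrfCall:
    frame: int          # 1, 2 or 3
    start_nt: int       # 0-based offset of the initiator codon
    protein: str
    complete_cds: bool  # a stop codon was observed


@dataclass(frozen=True)
class ClassLabel:
    """Major functional class (H/S/U) with a controlled subcategory."""

    major: str
    subcategory: str = ""

    def __post_init__(self):
        if self.major not in ("H", "S", "U"):
            raise ValueError(f"major class must be H, S or U, got {self.major!r}")
        if self.major == "U" and self.subcategory:
            raise ValueError("U class takes no subcategory")
        if self.major in ("H", "S") and not self.subcategory:
            raise ValueError(f"{self.major} class requires a subcategory")


@dataclass
class GeneRecord:
    """A transcript with its ORF, secretion flag, class and EST weight."""

    id: str
    seq: str
    orf: OrfCall | None
    secretion_flag: str  # yes | no | unknown
    label: ClassLabel
    est_count: int = 1


def three_frame_translate(seq: str) -> tuple[str, str, str]:
    """Standard-code translation of the three forward frames.

    Stops render as '*'; the trailing partial codon of each frame is
    dropped; codons containing N translate to X. No reverse-complement
    frames (directional library). Raises ValueError below 3 nt.
    """
    seq = seq.upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    out = []
    for frame in range(3):
        sub = seq[frame:]
        sub = sub[:len(sub) - len(sub) % 3]
        out.append(str(Seq(sub).translate()) if sub else "")
    return tuple(out)


def select_orf(translations, window: int = ORF_SEARCH_WINDOW) -> OrfCall | None:
    """Pick the reportable ORF from the three frame translations.

    Per frame the candidate runs from the first M within the first
    ``window`` residues to the first following stop (exclusive) or the
    end of the frame. The longest candidate wins; ties go to the lower
    frame. Returns None when no frame has an initiator Met in the window.
    """
    best: OrfCall | None = None
    for frame, prot in enumerate(translations, start=1):
        m = prot.find("M", 0, window)
        if m == -1:
            continue
        stop = prot.find("*", m)
        if stop == -1:
            candidate, complete = prot[m:], False
        else:
            candidate, complete = prot[m:stop], True
        if not candidate:
            continue
        if best is None or len(candidate) > len(best.protein):
            best = OrfCall(frame=frame, start_nt=(frame - 1) + 3 * m,
                           protein=candidate, complete_cds=complete)
    return best


def predict_secretion(protein: str, min_length: int = 25,
                      search_range: int = 30, min_h_window: int = 8,
                      cleavage_gap: int = 10) -> tuple[str, int]:
    """Heuristic signal-peptide call: (yes/no/unknown, h-window length).

    Within the first ``search_range`` residues an uninterrupted run of at
    least ``min_h_window`` hydrophobic residues (A,I,L,F,V,M,W,C) must be
    followed within ``cleavage_gap`` residues by a small residue
    (A,G,S,C,T) acting as a cleavage-like site. Proteins shorter than
    ``min_length`` return "unknown". This is a stand-in hook: when a real
    predictor's call is available in the evidence table it takes
    precedence (see :func:`annotate_records`).
    """
    protein = protein.upper()
    bad = set(protein) - AA_CHARS - {"*"}
    if bad:
        raise ValueError(f"non-amino-acid character(s): {sorted(bad)}")
    if len(protein) < min_length:
        return "unknown", 0
    head = protein[:search_range]
    run_start = None
    best = ("no", 0)
    for i, ch in enumerate(head + "$"):  # sentinel flushes the last run
        if ch in HYDROPHOBIC:
            if run_start is None:
                run_start = i
            continue
        if run_start is not None:
            run_len = i - run_start
            if run_len >= min_h_window:
                after = protein[i:i + cleavage_gap]
                if any(c in SMALL for c in after):
                    if run_len > best[1]:
                        best = ("yes", run_len)
            run_start = None
    return best


# ---------------------------------------------------------------------------
# Classification vocabulary and cascade

_UNINFORMATIVE = ("hypothetical", "unknown", "uncharacterized", "unnamed")
UNKNOWN_SECRETED = "Unknown secreted family"


def load_vocabulary() -> pd.DataFrame:
    """The keyword vocabulary (major, subcategory, keywords) data file."""
    ref = importlib.resources.files("sialome").joinpath("data/class_keywords.tsv")
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#").fillna("")
    return df


_VOCAB_CACHE = None


def _vocab() -> pd.DataFrame:
    global _VOCAB_CACHE
    if _VOCAB_CACHE is None:
        _VOCAB_CACHE = load_vocabulary()
    return _VOCAB_CACHE


def _informative(description: str) -> bool:
    d = description.strip().lower()
    if not d:
        return False
    return not any(w in d for w in _UNINFORMATIVE)


def _match_subcategory(description: str, major: str, vocab: pd.DataFrame
                       ) -> str | None:
    d = description.lower()
    for _, row in vocab[vocab["major"] == major].iterrows():
        for kw in filter(None, row["keywords"].split("|")):
            if kw in d:
                return row["subcategory"]
    return None


def _parse_hint(hint: str, vocab: pd.DataFrame) -> ClassLabel:
    if hint == "U":
        return ClassLabel("U")
    if ":" in hint:
        major, sub = hint.split(":", 1)
        major, sub = major.strip(), sub.strip()
        valid = set(vocab[vocab["major"] == major]["subcategory"])
        if major in ("H", "S") and sub in valid:
            return ClassLabel(major, sub)
    raise ValueError(f"category hint {hint!r} outside the closed vocabulary")


def classify(secretion_flag: str, evidence: EvidenceRow | None,
             vocab: pd.DataFrame | None = None) -> ClassLabel:
    """H/S/U classification cascade; first matching rule wins.

    1. a curator ``category_hint`` ("U" or "H:<sub>"/"S:<sub>") is taken
       verbatim (rejected if outside the vocabulary);
    2. secretion "yes" and a best hit matching a secreted-family keyword
       (or no informative hit at all) gives S;
    3. an informative hit matching a housekeeping subgroup keyword gives H;
    4. otherwise U.
    """
    vocab = _vocab() if vocab is None else vocab
    hit = evidence.best_hit_description if evidence else ""
    if evidence and evidence.category_hint:
        return _parse_hint(evidence.category_hint, vocab)
    if secretion_flag == "yes":
        sub = _match_subcategory(hit, "S", vocab) if _informative(hit) else None
        if sub:
            return ClassLabel("S", sub)
        if not _informative(hit):
            return ClassLabel("S", UNKNOWN_SECRETED)
    if _informative(hit):
        sub = _match_subcategory(hit, "H", vocab)
        if sub:
            return ClassLabel("H", sub)
        # an informative secreted-family hit without a secretion call still
        # identifies the family
        sub = _match_subcategory(hit, "S", vocab)
        if sub and secretion_flag != "no":
            return ClassLabel("S", sub)
    return ClassLabel("U")


def annotate_records(ests, evidence: dict | None = None,
                     vocab: pd.DataFrame | None = None,
                     est_counts: dict | None = None) -> list[GeneRecord]:
    """Full per-transcript annotation: ORF, secretion, classification.

    ``evidence`` maps id -> EvidenceRow; an explicit yes/no signal-peptide
    call there overrides the built-in heuristic. ``est_counts`` maps id ->
    cluster size (defaults to 1).
    """
    evidence = evidence or {}
    out = []
    for est in ests:
        ev = evidence.get(est.id)
        orf = select_orf(three_frame_translate(est.seq))
        if ev is not None and ev.signal_peptide in ("yes", "no"):
            flag = ev.signal_peptide
        elif orf is not None:
            flag, _ = predict_secretion(orf.protein)
        else:
            flag = "unknown"
        label = classify(flag, ev, vocab)
        out.append(GeneRecord(
            id=est.id, seq=est.seq, orf=orf, secretion_flag=flag, label=label,
            est_count=(est_counts or {}).get(est.id, 1)))
    return out


# ---------------------------------------------------------------------------
# Abundance tables


def _pct(count: int, total: int) -> float:
    from .abundance import percent_of_group
    return percent_of_group(count, total)


def category_table(records) -> dict[str, pd.DataFrame]:
    """EST-weighted class and subcategory abundance tables.

    Returns "major" (class, est_count, percent of library) plus one table
    per group with members ("H", "S"): subcategory EST counts and percent
    of group, to 1 decimal with half-up rounding.
    """
    records = list(records)
    total = sum(r.est_count for r in records)
    if total == 0:
        raise ValueError("no ESTs to tabulate")
    major_counts: dict[str, int] = {}
    sub_counts: dict[str, dict[str, int]] = {"H": {}, "S": {}}
    for r in records:
        major_counts[r.label.major] = (major_counts.get(r.label.major, 0)
                                       + r.est_count)
        if r.label.major in ("H", "S"):
            d = sub_counts[r.label.major]
            d[r.label.subcategory] = d.get(r.label.subcategory, 0) + r.est_count
    out = {}
    out["major"] = pd.DataFrame(
        [{"class": c, "est_count": n, "percent_of_library": _pct(n, total)}
         for c, n in sorted(major_counts.items())])
    for grp in ("H", "S"):
        gtotal = major_counts.get(grp, 0)
        rows = [{"subcategory": s, "est_count": n,
                 "percent_of_group": _pct(n, gtotal)}
                for s, n in sorted(sub_counts[grp].items(),
                                   key=lambda kv: (-kv[1], kv[0]))]
        if rows:
            out[grp] = pd.DataFrame(rows)
    return out
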