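"""EST clustering by exact-word-seeded ungapped overlaps.

Reads are grouped by single-linkage over accepted pairwise overlaps, the
way an assembly pipeline's cluster/singleton bookkeeping behaves: two
reads join when they share an exact seed word (default 36 nt) and extend
to an ungapped dovetail/containment overlap of at least 40 nt at >= 80%
identity. Each multi-read cluster gets a majority-rule consensus from the
overlap layout. Only forward-strand overlaps are considered by default
(directional libraries); ``both_strands`` adds reverse-complement seeding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

__all__ = [
    "ClusteringParams",
    "Overlap",
    "Cluster",
    "find_overlap",
    "cluster_reads",
    "consensus",
]

logger = logging.getLogger("sialome.cluster")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ClusteringParams:
    """Overlap acceptance parameters (seed word 36, overlap 40 at 80%)."""

    word_size: int = 36
    min_overlap: int = 40
    min_identity: float = 0.80
    both_strands: bool = False

    def __post_init__(self):
        if self.word_size < 8:
            raise ValueError("word_size must be >= 8")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class Overlap:
    """An ungapped overlap: b starts at ``offset`` in a's coordinates."""

    offset: int
    length: int
    identity: float


@dataclass
class Cluster:
    cluster_id: str
    member_ids: list[str]
    consensus: str
    is_singleton: bool


def _overlap_at(sa: str, sb: str, offset: int) -> tuple[int, float] | None:
    """Length and identity of the ungapped overlap at a fixed offset.

    Identity is computed over non-N columns; an overlap whose columns are
    all N has no usable identity and is rejected.
    """
    start_a = max(0, offset)
    end_a = min(len(sa), offset + len(sb))
    length = end_a - start_a
    if length <= 0:
        return None
    matches = compared = 0
    for i in range(start_a, end_a):
        x, y = sa[i], sb[i - offset]
        if x == "N" or y == "N":
            continue
        compared += 1
        if x == y:
            matches += 1
    if compared == 0:
        return None
    return length, matches / compared


def find_overlap(a, b, params: ClusteringParams = ClusteringParams()
                 ) -> Overlap | None:
    """Best accepted overlap between two reads, or None.

    Candidate offsets come from exact shared words of ``word_size`` nt;
    each candidate is scored ungapped over the full overlap and the
    highest-identity (then longest) one is returned if it passes the
    length and identity thresholds.
    """
    sa, sb = a.seq, b.seq
    k = params.word_size
    if len(sa) < k or len(sb) < k:
        return None
    index: dict[str, list[int]] = {}
    for i in range(len(sa) - k + 1):
        index.setdefault(sa[i:i + k], []).append(i)
    offsets = set()
    for j in range(len(sb) - k + 1):
        for i in index.get(sb[j:j + k], ()):
            offsets.add(i - j)
    best: Overlap | None = None
    for off in sorted(offsets):
        hit = _overlap_at(sa, sb, off)
        if hit is None:
            continue
        length, ident = hit
        if length < params.min_overlap or ident < params.min_identity:
            continue
        if (best is None or ident > best.identity
                or (ident == best.identity and length > best.length)):
            best = Overlap(offset=off, length=length, identity=ident)
    return best


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def cluster_reads(reads, params: ClusteringParams = ClusteringParams()
                  ) -> list[Cluster]:
    """Single-linkage clustering of reads over accepted overlaps.

    Candidate pairs are those sharing at least one exact seed word (a
    k-mer index avoids the all-pairs scan). Clusters are a partition of
    the input; cluster ids are assigned in order of the smallest member
    id. Raises ValueError on duplicate read ids.
    """
    reads = list(reads)
    ids = [r.id for r in reads]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate read id(s): {dup}")
    by_id = {r.id: r for r in reads}
    k = params.word_size

    index: dict[str, set[str]] = {}
    for r in reads:
        seen_words = set()
        for i in range(len(r.seq) - k + 1):
            seen_words.add(r.seq[i:i + k])
        if params.both_strands:
            rc = reverse_complement(r.seq)
            for i in range(len(rc) - k + 1):
                seen_words.add(rc[i:i + k])
        for w in seen_words:
            index.setdefault(w, set()).add(r.id)

    candidate_pairs = set()
    for members in index.values():
        if len(members) > 1:
            ms = sorted(members)
            for i in range(len(ms)):
                for j in range(i + 1, len(ms)):
                    candidate_pairs.add((ms[i], ms[j]))

    uf = _UnionFind(ids)
    overlaps: dict[tuple[str, str], Overlap] = {}
    for ia, ib in sorted(candidate_pairs):
        ov = find_overlap(by_id[ia], by_id[ib], params)
        if ov is None and params.both_strands:
            rc = type(by_id[ib])(id=ib, seq=reverse_complement(by_id[ib].seq),
                                 alphabet="nucleotide")
            ov = find_overlap(by_id[ia], rc, params)
        if ov is not None:
            overlaps[(ia, ib)] = ov
            uf.union(ia, ib)

    components: dict[str, list[str]] = {}
    for rid in ids:
        components.setdefault(uf.find(rid), []).append(rid)

    clusters = []
    ordered = sorted(components.values(), key=lambda ms: min(ms))
    for idx, members in enumerate(ordered, start=1):
        members = sorted(members)
        cons = consensus([by_id[m] for m in members], overlaps)
        clusters.append(Cluster(cluster_id=f"CL{idx:05d}",
                                member_ids=members,
                                consensus=cons,
                                is_singleton=(len(members) == 1)))
    return clusters


def consensus(members, overlaps: dict) -> str:
    """Majority-rule consensus of one cluster from its overlap layout.

    Offsets are propagated from the first member over the accepted-overlap
    graph. An edge whose implied offset conflicts with the layout already
    fixed is dropped with a warning (the documented fallback when a cycle
    is inconsistent); the consensus then covers the component reachable
    from the smallest member id. Per column the majority base wins, ties
    broken A < C < G < T; N columns count only when nothing else is there.
    """
    members = sorted(members, key=lambda r: r.id)
    if len(members) == 1:
        return members[0].seq
    ids = [r.id for r in members]
    by_id = {r.id: r for r in members}
    adj: dict[str, list[tuple[str, int]]] = {i: [] for i in ids}
    for (ia, ib), ov in overlaps.items():
        if ia in by_id and ib in by_id:
            adj[ia].append((ib, ov.offset))
            adj[ib].append((ia, -ov.offset))

    pos = {ids[0]: 0}
    queue = [ids[0]]
    while queue:
        cur = queue.pop(0)
        for nb, off in sorted(adj[cur]):
            want = pos[cur] + off
            if nb in pos:
                if pos[nb] != want:
                    logger.warning(
                        "inconsistent layout offset between %s and %s "
                        "(%d vs %d); edge dropped", cur, nb, pos[nb], want)
                continue
            pos[nb] = want
            queue.append(nb)

    placed = sorted(pos)
    if len(placed) < len(ids):
        logger.warning("cluster layout split: %d of %d reads placed",
                       len(placed), len(ids))
    lo = min(pos[i] for i in placed)
    hi = max(pos[i] + len(by_id[i].seq) for i in placed)
    length = hi - lo
    cols: list[dict[str, int]] = [dict() for _ in range(length)]
    for rid in placed:
        start = pos[rid] - lo
        for i, base in enumerate(by_id[rid].seq):
            col = cols[start + i]
            col[base] = col.get(base, 0) + 1
    out = []
    for col in cols:
        real = {b: c for b, c in col.items() if b != "N"}
        if real:
            best = max(real.values())
            out.append(min(b for b, c in real.items() if c == best))
        elif col:
            out.append("N")
        else:
            out.append("N")  # uncovered gap inside the layout
    return "".join(out)
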