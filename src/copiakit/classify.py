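"""RT clone processing: frameshift-aware translation, core trimming,
peptide p-distances, neighbor joining, family cutting, and the family
distribution homogeneity test.

Cloned RT amplicons carry occasional spontaneous frameshifts; translation
runs a dynamic program over the three frames with a per-shift penalty and
reports the longest stop-free peptide.  Clones are stacked by an anchored
star alignment, trimmed to their shared core (~75 aa), clustered by
single-linkage on peptide p-distance, and compared across accessions with a
Pearson chi-square test.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency

from ._seq import revcomp, translate


@dataclass
class RTClone:
    id: str
    accession: str
    primer_set: str
    nt: str
    aa: str = ""
    frameshift_events: int = 0


@dataclass
class ClassifyParams:
    core_len: int = 75           # amino acids, the shared trimmed block
    family_cut: float = 0.40     # peptide p-distance, single linkage
    bootstrap_n: int = 100
    frameshift_penalty: int = 4  # codons charged per frame switch
    min_peptide: int = 20        # shorter translations classify as non-RT

    def __post_init__(self):
        if self.core_len < 30:
            raise ValueError("core_len must be >= 30")
        if not 0.0 < self.family_cut < 1.0:
            raise ValueError("family_cut must lie in (0, 1)")


# ---------------------------------------------------------------------------
# translation with frameshift recovery


def translate_with_frameshift_recovery(nt: str, penalty: int = 4,
                                       min_aa: int = 20, max_events: int = 2,
                                       stop_penalty: int = 3,
                                       max_stops: int = 2) -> tuple[str, int] | None:
    """Longest credible peptide over the three frames, allowing frame shifts.

    A dynamic program chains codons with steps of 3 (same frame) or 2/4 nt
    (one frameshift event, charged ``penalty`` codons), maximizing encoded
    length with at most ``max_events`` shifts — spontaneous frameshifts are
    rare single mutations, not free frame hopping.  Up to ``max_stops``
    in-frame stop codons may be read through as 'X' (nonsense codons arise
    from single substitutions and should not derail the frame).  Both
    strands are tried; returns ``(peptide, events)`` or None when no path
    reaches ``min_aa`` residues (non-RT clone).
    """
    if len(nt) < 60:
        raise ValueError("sequence shorter than 60 nt")
    best = None
    for strand_seq in (nt.upper(), revcomp(nt.upper())):
        res = _frameshift_dp(strand_seq, penalty, max_events, stop_penalty, max_stops)
        if res is not None and (best is None or res[0] > best[0]):
            best = res
    if best is None:
        return None
    _, pep, events = best
    if len(pep.strip("X")) < min_aa:
        return None
    return pep, events


def _frameshift_dp(nt: str, penalty: int, max_events: int,
                   stop_penalty: int, max_stops: int):
    n = len(nt)
    kind = []                    # 1 = regular codon, 0 = stop (read-through), -1 = bad
    for p in range(n - 2):
        codon = nt[p:p + 3]
        if "N" in codon:
            kind.append(-1)
        elif codon in ("TAA", "TAG", "TGA"):
            kind.append(0)
        else:
            kind.append(1)
    m = len(kind)
    NEG = -(1 << 30)
    ne, ns = max_events + 1, max_stops + 1
    score = [[[NEG] * ns for _ in range(ne)] for _ in range(m)]
    parent = [[[None] * ns for _ in range(ne)] for _ in range(m)]
    best_key, best_state = None, None
    for p in range(m):
        if kind[p] < 0:
            continue
        is_stop = kind[p] == 0
        gain = 1 - (stop_penalty if is_stop else 0)
        for e in range(ne):
            for s in range(ns):
                if is_stop and s == 0:
                    continue
                ps = s - (1 if is_stop else 0)
                # a path may start fresh at p (then e = 0 and s counts only p itself)
                cur, par = (gain, None) if (e == 0 and ps == 0) else (NEG, None)
                for prev, shift in ((p - 3, 0), (p - 2, 1), (p - 4, 1)):
                    pe = e - shift
                    if prev >= 0 and pe >= 0 and score[prev][pe][ps] > NEG:
                        cand = score[prev][pe][ps] + gain - penalty * shift
                        if cand > cur:
                            cur, par = cand, (prev, pe, ps)
                if cur > NEG:
                    score[p][e][s] = cur
                    parent[p][e][s] = par
                    key = (cur, -e - s, -p)
                    if best_key is None or key > best_key:
                        best_key, best_state = key, (p, e, s)
    if best_state is None:
        return None
    path = []
    state = best_state
    while state is not None:
        path.append(state[0])
        state = parent[state[0]][state[1]][state[2]]
    path.reverse()
    pep = "".join("X" if kind[q] == 0 else translate(nt[q:q + 3]) for q in path)
    n_events = sum(1 for a, b in zip(path[:-1], path[1:]) if b - a != 3)
    return best_key[0], pep, n_events


# conserved RT peptide anchors (the primer-encoded motifs); a clone's chosen
# reading must resemble one of them to count as an identifiable RT sequence
RT_ANCHOR_PEPTIDES = ("TAFLHG", "QMDVKTGSF", "YVDDML")


def _anchor_score(pep: str) -> int:
    """Best (length - mismatches) over all anchor placements; higher = more RT-like."""
    best = 0
    for anchor in RT_ANCHOR_PEPTIDES:
        k = len(anchor)
        for i in range(len(pep) - k + 1):
            m = sum(a == b for a, b in zip(pep[i:i + k], anchor))
            best = max(best, 2 * m - k)
    return best


def rt_identifiable(pep: str) -> bool:
    """True when some RT anchor matches with at most ~1/4 mismatches."""
    return any(
        max((sum(a == b for a, b in zip(pep[i:i + len(anchor)], anchor))
             for i in range(max(1, len(pep) - len(anchor) + 1))), default=0)
        >= len(anchor) - max(1, len(anchor) // 4)
        for anchor in RT_ANCHOR_PEPTIDES)


def clone_from_amplicon(clone_id: str, accession: str, primer_set: str, nt: str,
                        params: ClassifyParams | None = None) -> RTClone | None:
    """Build an RTClone; non-RT sequences are dropped.

    The frameshift-aware translation is used when its peptide is
    identifiable as RT; otherwise the six straight-frame read-through
    translations are tried (a frame whose accidental stop-free reading
    outscored the true frame is overridden by the anchor check), and a
    clone with no identifiable reading is discarded — mirroring the ~2%
    of cloned fragments that are not recognizable RT sequences.
    """
    params = params or ClassifyParams()
    res = translate_with_frameshift_recovery(nt, params.frameshift_penalty, params.min_peptide)
    if res is not None and rt_identifiable(res[0]):
        return RTClone(clone_id, accession, primer_set, nt, res[0], res[1])
    candidates = []
    for strand_seq in (nt.upper(), revcomp(nt.upper())):
        for frame in range(3):
            pep = translate(strand_seq[frame:]).replace("*", "X")
            if pep.count("X") <= 2 and len(pep) >= params.min_peptide and rt_identifiable(pep):
                candidates.append((_anchor_score(pep), -pep.count("X"), pep))
    if not candidates:
        return None
    _, negx, pep = max(candidates)
    return RTClone(clone_id, accession, primer_set, nt, pep, 0)


# ---------------------------------------------------------------------------
# alignment and distances


def _pairwise_offset(ref: str, pep: str, min_overlap: int = 10) -> int:
    best_off, best_score = 0, -1
    for off in range(-(len(pep) - min_overlap), len(ref) - min_overlap + 1):
        lo = max(0, off)
        hi = min(len(ref), off + len(pep))
        if hi - lo < min_overlap:
            continue
        score = sum(ref[i] == pep[i - off] for i in range(lo, hi))
        if score > best_score:
            best_score, best_off = score, off
    return best_off


def _star_align(peps: list[str]) -> list[str]:
    """Ungapped star alignment against the longest sequence; '-' padded rows."""
    ref_idx = max(range(len(peps)), key=lambda i: len(peps[i]))
    offsets = [_pairwise_offset(peps[ref_idx], p) for p in peps]
    lo = min(offsets)
    hi = max(off + len(p) for off, p in zip(offsets, peps))
    return ["-" * (off - lo) + p + "-" * (hi - off - len(p))
            for off, p in zip(offsets, peps)]


@dataclass
class AlignedBlock:
    rows: list[str]
    ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def trim_to_core(clones: list[RTClone], params: ClassifyParams | None = None,
                 coverage: float = 0.95) -> AlignedBlock:
    """Align clone peptides and trim to the block covered by >=``coverage``.

    The reported block is the longest contiguous run of columns covered by
    at least that fraction of clones — the clones' shared core region.
    """
    params = params or ClassifyParams()
    if len(clones) < 3:
        raise ValueError("need at least 3 clones to define a core block")
    rows = _star_align([c.aa for c in clones])
    arr = np.array([list(r) for r in rows])
    cov = (arr != "-").mean(axis=0)
    good = cov >= coverage
    # longest contiguous qualifying run
    best = (0, 0)
    i = 0
    while i < good.size:
        if good[i]:
            j = i
            while j < good.size and good[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    lo, hi = best
    return AlignedBlock(rows=[r[lo:hi] for r in rows], ids=[c.id for c in clones])


def p_distance_matrix(block) -> np.ndarray:
    """Pairwise p-distance (mismatches / compared columns, gaps deleted pairwise)."""
    rows = block.rows if isinstance(block, AlignedBlock) else list(block)
    arr = np.array([list(r) for r in rows])
    n = arr.shape[0]
    gap = arr == "-"
    D = np.zeros((n, n))
    for i in range(n):
        both = ~gap[i] & ~gap
        diff = (arr[i] != arr) & both
        comp = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(comp > 0, diff.sum(axis=1) / np.maximum(comp, 1), 1.0)
        D[i] = d
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# neighbor joining


class TreeNode:
    """Rooted tree view node."""

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = length
        self.children: list["TreeNode"] = []
        self.parent: "TreeNode | None" = None

    def add(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def tip_names(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.tip_names())
        return out

    def find(self, name: str) -> "TreeNode | None":
        if not self.children and self.name == name:
            return self
        for c in self.children:
            hit = c.find(name)
            if hit is not None:
                return hit
        return None

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._nwk() for c in self.children)
        return f"({inner}):{self.length:.6g}"


class Tree:
    """Unrooted tree as an adjacency map; tips carry labels."""

    def __init__(self):
        self.adj: dict[int, list[tuple[int, float]]] = {}
        self.names: dict[int, str] = {}
        self._next = 0

    def new_node(self, name: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = []
        if name is not None:
            self.names[nid] = name
        return nid

    def link(self, a: int, b: int, length: float) -> None:
        self.adj[a].append((b, length))
        self.adj[b].append((a, length))

    def tip_ids(self) -> list[int]:
        return sorted(self.names)

    def _build(self, nid: int, parent: int | None, length: float) -> TreeNode:
        node = TreeNode(self.names.get(nid), length)
        for nbr, bl in self.adj[nid]:
            if nbr != parent:
                node.add(self._build(nbr, nid, bl))
        return node

    def rooted_at(self, tip_name: str) -> TreeNode:
        """Root on the edge leading to the named tip."""
        tip_id = next(i for i, n in self.names.items() if n == tip_name)
        (nbr, bl), = self.adj[tip_id]
        root = TreeNode()
        root.add(self._build(tip_id, nbr, bl / 2))
        root.add(self._build(nbr, tip_id, bl / 2))
        return root

    def newick(self) -> str:
        start = next(i for i in self.adj if i not in self.names) if \
            len(self.adj) > len(self.names) else next(iter(self.adj))
        return self._build(start, None, 0.0).newick()

    def splits(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions as frozensets of tip names (smaller side)."""
        all_tips = frozenset(self.names.values())
        out = set()
        for a in self.adj:
            for b, _ in self.adj[a]:
                if a < b:
                    side = frozenset(self._side_tips(b, a))
                    if 1 < len(side) < len(all_tips) - 1:
                        out.add(min(side, all_tips - side, key=lambda s: (len(s), sorted(s))))
        return out

    def _side_tips(self, nid: int, parent: int) -> list[str]:
        out = [self.names[nid]] if nid in self.names else []
        for nbr, _ in self.adj[nid]:
            if nbr != parent:
                out.extend(self._side_tips(nbr, nid))
        return out

    def distance_matrix(self, labels: list[str]) -> np.ndarray:
        """Path-length distances between the named tips."""
        ids = {n: i for i, n in self.names.items()}
        n = len(labels)
        D = np.zeros((n, n))
        for i, a in enumerate(labels):
            dist = {ids[a]: 0.0}
            stack = [ids[a]]
            while stack:
                u = stack.pop()
                for v, bl in self.adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + bl
                        stack.append(v)
            for j, b in enumerate(labels):
                D[i, j] = dist[ids[b]]
        return D


def neighbor_joining(D, labels: list[str] | None = None) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Joins the pair minimizing the Q-criterion (lowest index pair on ties);
    branch lengths from the rate-corrected formula, negatives clamped to 0
    with the deficit moved to the sister edge.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    labels = labels or [f"t{i}" for i in range(n)]
    tree = Tree()
    nodes = [tree.new_node(lbl) for lbl in labels]
    mat = D.copy()
    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sub = mat[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        Q = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(Q, np.inf)
        bi, bj, bq = -1, -1, np.inf
        for i in range(r):
            for j in range(i + 1, r):
                if Q[i, j] < bq:
                    bq, bi, bj = Q[i, j], i, j
        dij = sub[bi, bj]
        li = dij / 2 + (rowsum[bi] - rowsum[bj]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            lj, li = dij, 0.0
        if lj < 0:
            li, lj = dij, 0.0
        u = tree.new_node()
        tree.link(nodes[active[bi]], u, li)
        tree.link(nodes[active[bj]], u, lj)
        new_id = mat.shape[0]
        du = (mat[active[bi]] + mat[active[bj]] - dij) / 2
        mat = np.pad(mat, ((0, 1), (0, 1)))
        mat[new_id, :new_id] = du
        mat[:new_id, new_id] = du
        nodes.append(u)
        hi, lo = max(bi, bj), min(bi, bj)
        active.pop(hi)
        active.pop(lo)
        active.append(new_id)
    a, b, c = active
    center = tree.new_node()
    la = (mat[a, b] + mat[a, c] - mat[b, c]) / 2
    lb = mat[a, b] - la
    lc = mat[a, c] - la
    for tip, bl in ((a, la), (b, lb), (c, lc)):
        tree.link(nodes[tip], center, max(bl, 0.0))
    return tree


# ---------------------------------------------------------------------------
# family cutting and distribution test


@dataclass
class FamilyAssignment:
    families: dict[str, str]     # clone id -> family label
    tree: Tree | None
    labels: list[str]

    @property
    def n_families(self) -> int:
        return len(set(self.families.values()))


def cut_families(D, ids: list[str], family_cut: float = 0.40,
                 tree: Tree | None = None, prefix: str = "Jc") -> FamilyAssignment:
    """Single-linkage clustering of the p-distance matrix at ``family_cut``.

    Families are labelled ``Jc1..Jck`` by descending clone count (ties by
    first appearance).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n != len(ids):
        raise ValueError("ids must match the matrix")
    if n == 1:
        flat = np.array([1])
    else:
        Z = linkage(squareform(D, checks=False), method="single")
        flat = fcluster(Z, t=family_cut, criterion="distance")
    order: dict[int, tuple[int, int]] = {}
    for pos, c in enumerate(flat):
        cnt, first = order.get(c, (0, pos))
        order[c] = (cnt + 1, first)
    ranked = sorted(order, key=lambda c: (-order[c][0], order[c][1]))
    rename = {c: f"{prefix}{k + 1}" for k, c in enumerate(ranked)}
    fams = {cid: rename[c] for cid, c in zip(ids, flat)}
    if tree is None and n >= 3:
        tree = neighbor_joining(D, ids)
    return FamilyAssignment(families=fams, tree=tree, labels=ids)


def family_distribution_test(counts) -> tuple[float, int, float]:
    """Pearson chi-square homogeneity test on an accession x family table."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.size == 0:
        raise ValueError("need a 2-D contingency table")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected == 0).any():
        raise ValueError("expected count of zero; pool sparse rows/columns before testing")
    chi2, p, df, _ = chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
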