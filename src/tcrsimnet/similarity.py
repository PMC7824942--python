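"""Length-normalized Levenshtein similarity (L-sim) and threshold clustering.

L-sim between two strings is ``1 - d / max(len_a, len_b)`` where ``d`` is
the unit-cost Levenshtein edit distance, giving a score in [0, 1] with 1
for identical sequences.  Scores are derived from exact integer distances
and integer lengths, so threshold comparisons are reproducible without
floating-point tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONCAT_AB = "concat_ab"
PER_CHAIN_MEAN = "per_chain_mean"
BETA_ONLY = "beta_only"

_MODES = (CONCAT_AB, PER_CHAIN_MEAN, BETA_ONLY)


def _char_masks(pattern: str) -> dict[str, int]:
    peq: dict[str, int] = {}
    for i, c in enumerate(pattern):
        peq[c] = peq.get(c, 0) | (1 << i)
    return peq


def _myers_distance(peq: dict[str, int], m: int, text: str) -> int:
    """Bit-parallel Levenshtein distance (Myers/Hyyrö).

    ``peq``/``m`` describe the pattern; Python's arbitrary-precision
    integers remove the usual word-size limit.
    """
    mask = (1 << m) - 1
    high = 1 << (m - 1)
    vp = mask
    vn = 0
    dist = m
    for c in text:
        eq = peq.get(c, 0)
        d0 = (((eq & vp) + vp) ^ vp) | eq | vn
        hp = vn | (~(d0 | vp) & mask)
        hn = vp & d0
        if hp & high:
            dist += 1
        if hn & high:
            dist -= 1
        x = ((hp << 1) | 1) & mask
        vn = x & d0
        vp = ((hn << 1) & mask) | (~(x | d0) & mask)
    return dist


def levenshtein_distance(a: str, b: str) -> int:
    """Unit-cost edit distance between two strings.

    Symmetric, non-negative, zero iff equal, and satisfies the triangle
    inequality.  Uses a bit-parallel algorithm; exact for all inputs.
    """
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):
        a, b = b, a
    return _myers_distance(_char_masks(a), len(a), b)


def lsim(a: str, b: str) -> float:
    """L-sim score: ``1 - levenshtein_distance(a, b) / max(|a|, |b|)``.

    Raises
    ------
    ValueError
        If both strings are empty (score undefined).
    """
    if not a and not b:
        raise ValueError("lsim undefined for two empty strings")
    return 1.0 - levenshtein_distance(a, b) / max(len(a), len(b))


@dataclass
class SimilarityMatrix:
    """Condensed symmetric matrix of pairwise L-sim scores.

    Scores are stored as the upper triangle in scipy's condensed order;
    the diagonal is implicitly 1.
    """

    clonotype_order: list[str]
    scores: np.ndarray  # condensed, length n*(n-1)//2
    pairing_mode: str

    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        n = len(self.clonotype_order)
        if len(self.scores) != n * (n - 1) // 2:
            raise ValueError("condensed score length does not match clonotype count")
        self._index = {cid: i for i, cid in enumerate(self.clonotype_order)}

    @property
    def n(self) -> int:
        return len(self.clonotype_order)

    def _condensed_idx(self, i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        n = self.n
        return n * i - i * (i + 1) // 2 + (j - i - 1)

    def get(self, id_i: str, id_j: str) -> float:
        """Symmetric score lookup by clonotype id; diagonal is 1.0."""
        i, j = self._index[id_i], self._index[id_j]
        if i == j:
            return 1.0
        return float(self.scores[self._condensed_idx(i, j)])

    def iter_pairs(self):
        """Yield (id_i, id_j, score) over all unordered off-diagonal pairs."""
        n = self.n
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                yield self.clonotype_order[i], self.clonotype_order[j], float(self.scores[k])
                k += 1

    def to_long_frame(self) -> pd.DataFrame:
        rows = [(a, b, s) for a, b, s in self.iter_pairs()]
        return pd.DataFrame(rows, columns=["id_i", "id_j", "lsim"])

    def to_square_frame(self) -> pd.DataFrame:
        n = self.n
        square = np.ones((n, n))
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                square[i, j] = square[j, i] = self.scores[k]
                k += 1
        return pd.DataFrame(square, index=self.clonotype_order, columns=self.clonotype_order)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, pairing_mode: str = CONCAT_AB) -> "SimilarityMatrix":
        order: list[str] = []
        seen: set[str] = set()
        for col in ("id_i", "id_j"):
            for cid in df[col].astype(str):
                if cid not in seen:
                    seen.add(cid)
                    order.append(cid)
        order = sorted(order)
        idx = {cid: i for i, cid in enumerate(order)}
        n = len(order)
        scores = np.zeros(n * (n - 1) // 2)
        for row in df.itertuples(index=False):
            i, j = idx[str(row.id_i)], idx[str(row.id_j)]
            if i == j:
                continue
            if i > j:
                i, j = j, i
            scores[n * i - i * (i + 1) // 2 + (j - i - 1)] = float(row.lsim)
        return cls(clonotype_order=order, scores=scores, pairing_mode=pairing_mode)


def _pair_strings(clonotypes, mode: str) -> list[tuple]:
    if mode == CONCAT_AB:
        for ct in clonotypes:
            if not ct.cdr3a:
                raise ValueError(
                    f"clonotype {ct.clonotype_id} lacks cdr3a; concat_ab needs paired chains"
                )
        return [(ct.cdr3a + ct.cdr3b,) for ct in clonotypes]
    if mode == PER_CHAIN_MEAN:
        for ct in clonotypes:
            if not ct.cdr3a:
                raise ValueError(
                    f"clonotype {ct.clonotype_id} lacks cdr3a; per_chain_mean needs paired chains"
                )
        return [(ct.cdr3a, ct.cdr3b) for ct in clonotypes]
    return [(ct.cdr3b,) for ct in clonotypes]


def pairwise_lsim(clonotypes, pairing_mode: str = CONCAT_AB) -> SimilarityMatrix:
    """Compute L-sim for all unordered clonotype pairs.

    ``concat_ab`` (default) scores alpha+beta concatenated without a
    separator; ``per_chain_mean`` averages the per-chain scores;
    ``beta_only`` scores cdr3b alone.
    """
    if pairing_mode not in _MODES:
        raise ValueError(f"unknown pairing mode {pairing_mode!r}")
    if len(clonotypes) < 2:
        raise ValueError("need at least 2 clonotypes for pairwise similarity")
    strings = _pair_strings(clonotypes, pairing_mode)
    n = len(clonotypes)
    scores = np.empty(n * (n - 1) // 2)
    k = 0
    # precompute pattern bitmasks once per row sequence
    if pairing_mode == PER_CHAIN_MEAN:
        for i in range(n):
            ai, bi = strings[i]
            pa, pb = _char_masks(ai), _char_masks(bi)
            ma, mb = len(ai), len(bi)
            for j in range(i + 1, n):
                aj, bj = strings[j]
                da = _myers_distance(pa, ma, aj) if ai != aj else 0
                db = _myers_distance(pb, mb, bj) if bi != bj else 0
                sa = 1.0 - da / max(ma, len(aj))
                sb = 1.0 - db / max(mb, len(bj))
                scores[k] = (sa + sb) / 2.0
                k += 1
    else:
        seqs = [s[0] for s in strings]
        for i in range(n):
            si = seqs[i]
            peq, m = _char_masks(si), len(si)
            for j in range(i + 1, n):
                sj = seqs[j]
                d = 0 if si == sj else _myers_distance(peq, m, sj)
                scores[k] = 1.0 - d / max(m, len(sj))
                k += 1
    return SimilarityMatrix(
        clonotype_order=[ct.clonotype_id for ct in clonotypes],
        scores=scores,
        pairing_mode=pairing_mode,
    )


def lsim_distribution(matrix: SimilarityMatrix, bin_width: float = 0.05) -> dict:
    """Summarize the off-diagonal L-sim score distribution.

    Returns histogram counts over [0, 1] plus mean, sd, quantiles, and
    the fraction of pairs above 0.8.
    """
    scores = np.asarray(matrix.scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty similarity matrix")
    nbins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    counts, _ = np.histogram(scores, bins=edges)
    q = np.quantile(scores, [0.0, 0.25, 0.5, 0.75, 1.0])
    return {
        "n_pairs": int(scores.size),
        "bin_edges": edges.tolist(),
        "counts": counts.tolist(),
        "mean": float(scores.mean()),
        "sd": float(scores.std(ddof=1)) if scores.size > 1 else 0.0,
        "quantiles": {"min": q[0], "q25": q[1], "median": q[2], "q75": q[3], "max": q[4]},
        "fraction_above_0.8": float((scores > 0.8).mean()),
    }


@dataclass
class SimilarityCluster:
    """A connected component of the score > tau similarity graph (>= 2 members)."""

    cluster_id: str
    members: list[str]
    member_meta: list[dict] = field(default_factory=list)
    min_lsim: float = 1.0
    max_lsim: float = 1.0


def threshold_clusters(
    matrix: SimilarityMatrix, tau: float, clonotypes=None
) -> list[SimilarityCluster]:
    """Connected components of the graph with edges where L-sim > tau (strict).

    Components with >= 2 members are returned sorted by size descending,
    ties by lexicographically smallest member id.  If ``clonotypes`` is
    given, member metadata (cdr3a/cdr3b/sample/group) is attached.
    """
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must be in (0, 1)")
    n = matrix.n
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.scores[k] > tau:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
            k += 1
    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)
    meta_by_id = {}
    if clonotypes is not None:
        for ct in clonotypes:
            meta_by_id[ct.clonotype_id] = {
                "cdr3a": ct.cdr3a or "",
                "cdr3b": ct.cdr3b,
                "size": ct.size,
                "samples": ";".join(sorted(ct.samples)),
                "groups": ";".join(sorted(ct.groups)),
            }
    raw = [sorted(matrix.clonotype_order[i] for i in comp) for comp in components.values() if len(comp) >= 2]
    raw.sort(key=lambda ms: (-len(ms), ms[0]))
    clusters = []
    for idx, members in enumerate(raw):
        pair_scores = [
            matrix.get(a, b) for x, a in enumerate(members) for b in members[x + 1 :]
        ]
        above = [s for s in pair_scores if s > tau]
        clusters.append(
            SimilarityCluster(
                cluster_id=f"cluster{idx + 1}",
                members=members,
                member_meta=[meta_by_id.get(m, {}) for m in members],
                min_lsim=min(above) if above else float("nan"),
                max_lsim=max(above) if above else float("nan"),
            )
        )
    return clusters


def clusters_to_frame(clusters: list[SimilarityCluster]) -> pd.DataFrame:
    rows = []
    for cluster in clusters:
        for member, meta in zip(cluster.members, cluster.member_meta):
            row = {"cluster_id": cluster.cluster_id, "clonotype_id": member}
            row.update(meta)
            rows.append(row)
    cols = ["cluster_id", "clonotype_id", "cdr3a", "cdr3b", "size", "samples", "groups"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = ""
    return df[cols] if len(df) else pd.DataFrame(columns=cols)
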