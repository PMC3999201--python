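"""Alignment handling, deduplication, K2P distances and threshold clustering.

Implements the sequence side of the delimitation workflow: reading an
aligned COI-like FASTA, collapsing sequences that are identical up to
undetermined residues (N), Kimura 2-parameter distances with pairwise
deletion, single-linkage clustering at a similarity threshold (99% by
default), and a transition/transversion saturation profile.
"""
from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "DedupReport",
    "AlignmentFormatError",
    "NoOverlapError",
    "SaturatedPairWarning",
    "read_fasta",
    "write_fasta",
    "dedup_longest",
    "k2p",
    "k2p_matrix",
    "threshold_clusters",
    "saturation_profile",
]

_ALPHABET = "ACGTN-"
# integer codes: A=0 C=1 G=2 T=3, N=4, gap=5
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_PURINE = frozenset("AG")


class AlignmentFormatError(ValueError):
    pass


class NoOverlapError(ValueError):
    """Two sequences share no site where both are determinate."""


class SaturatedPairWarning(UserWarning):
    pass


@dataclass
class Alignment:
    """Named, equal-length sequences over {A, C, G, T, N, -}."""

    records: list[tuple[str, str]]

    def __post_init__(self):
        if not self.records:
            raise AlignmentFormatError("alignment is empty")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"sequences have unequal lengths: {sorted(lengths)}")
        if next(iter(lengths)) == 0:
            raise AlignmentFormatError("sequences have zero length")
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            raise AlignmentFormatError("duplicate sequence ids")
        bad = set("".join(s for _, s in self.records)) - set(_ALPHABET)
        if bad:
            raise AlignmentFormatError(f"invalid symbols: {sorted(bad)}")

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def __len__(self) -> int:
        return len(self.records)

    def matrix(self) -> np.ndarray:
        """(n, L) uint8 matrix of integer-coded residues."""
        lut = np.zeros(128, dtype=np.uint8)
        for c, i in _CODE.items():
            lut[ord(c)] = i
        raw = np.frombuffer("".join(s for _, s in self.records).encode(),
                            dtype=np.uint8)
        return lut[raw].reshape(len(self), self.length)


def _normalize_seq(seq: str, rec_id: str) -> str:
    out = []
    warned: set[str] = set()
    for ch in seq.upper():
        if ch in _ALPHABET:
            out.append(ch)
        elif ch == "U":
            out.append("T")
        else:
            if ch not in warned:
                warnings.warn(f"record {rec_id}: symbol {ch!r} mapped to N",
                              UserWarning)
                logger.warning("record %s: symbol %r mapped to N", rec_id, ch)
                warned.add(ch)
            out.append("N")
    return "".join(out)


def read_fasta(path: str | os.PathLike) -> Alignment:
    """Read an aligned FASTA; lowercase -> uppercase, U -> T, other -> N."""
    records = [(rec.id, _normalize_seq(str(rec.seq), rec.id))
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentFormatError(f"no sequences found in {path}")
    return Alignment(records)


def write_fasta(alignment: Alignment, path: str | os.PathLike,
                wrap: int = 70) -> None:
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in alignment.records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(recs)


@dataclass
class DedupReport:
    """Groups collapsed by :func:`dedup_longest`: (kept_id, [collapsed ids])."""

    groups: list[tuple[str, list[str]]]

    def collapsed(self) -> dict[str, str]:
        """Map from every removed id to the id kept in its place."""
        return {m: kept for kept, members in self.groups for m in members
                if m != kept}


def dedup_longest(alignment: Alignment) -> tuple[Alignment, DedupReport]:
    """Collapse sequences identical up to undetermined residues.

    Two sequences are *compatible* when they agree at every aligned
    position where both carry a determinate character (A, C, G, T or the
    gap); N acts as a wildcard. Compatibility is not transitive, so the
    connected components of the compatibility graph are collapsed; within
    each component the sequence with the most determinate (non-N, non-gap)
    characters is kept, ties broken by input order. Representatives keep
    their input order.
    """
    mat = alignment.matrix()
    n = len(alignment)
    n_code = _CODE["N"]
    det = mat != n_code  # determinate incl. gap (wildcard is N only)
    # adjacency: no position where both determinate and different
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        both = det[i] & det[i + 1:]
        diff = (mat[i] != mat[i + 1:]) & both
        adj[i, i + 1:] = ~diff.any(axis=1)
    adj |= adj.T
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    coverage = ((mat != n_code) & (mat != _CODE["-"])).sum(axis=1)
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)
    reps = {lab: max(members, key=lambda i: (coverage[i], -i))
            for lab, members in groups.items()}
    kept_rows = sorted(reps.values())
    report_groups = [(alignment.ids[row],
                      [alignment.ids[m] for m in groups[int(labels[row])]])
                     for row in kept_rows]
    deduped = Alignment([alignment.records[i] for i in kept_rows])
    return deduped, DedupReport(report_groups)


def _count_pair(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(m, transitions, transversions) after pairwise deletion."""
    ok = (a < 4) & (b < 4)
    m = int(ok.sum())
    diff = ok & (a != b)
    purine_a = (a == 0) | (a == 2)
    purine_b = (b == 0) | (b == 2)
    ts = int((diff & (purine_a == purine_b)).sum())
    tv = int(diff.sum()) - ts
    return m, ts, tv


def _k2p_from_counts(m: int, s: int, v: int) -> tuple[float, float, float, bool]:
    """Return (d, P, Q, saturated)."""
    P, Q = s / m, v / m
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return np.nan, P, Q, True
    return -0.5 * np.log(w1) - 0.25 * np.log(w2), P, Q, False


def k2p(seq_a: str, seq_b: str) -> tuple[float, float, float, int]:
    """Kimura 2-parameter distance between two aligned sequences.

    Sites where either sequence carries N or a gap are deleted pairwise.
    Returns ``(d, P, Q, m)`` with P and Q the transition and transversion
    proportions over the m retained sites and
    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

    Raises :class:`NoOverlapError` when m = 0; emits
    :class:`SaturatedPairWarning` (d = NaN) when a log argument is <= 0.
    """
    aln = Alignment([("a", seq_a.upper()), ("b", seq_b.upper())])
    mat = aln.matrix()
    m, s, v = _count_pair(mat[0], mat[1])
    if m == 0:
        raise NoOverlapError("sequences share no determinate overlapping sites")
    d, P, Q, saturated = _k2p_from_counts(m, s, v)
    if saturated:
        warnings.warn("saturated pair: K2P distance undefined",
                      SaturatedPairWarning)
    return d, P, Q, m


@dataclass
class DistanceMatrix:
    """Pairwise K2P distances plus the site counts behind them.

    ``d`` is symmetric with zero diagonal (NaN marks saturated pairs,
    flagged in ``defined``); ``m``, ``s``, ``v`` hold effective sites,
    transitions and transversions; ``P`` and ``Q`` the corresponding
    proportions.
    """

    ids: list[str]
    d: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    m: np.ndarray
    s: np.ndarray
    v: np.ndarray
    defined: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def to_long_dataframe(self) -> pd.DataFrame:
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({
                    "id_a": self.ids[i], "id_b": self.ids[j],
                    "d": self.d[i, j], "P": self.P[i, j], "Q": self.Q[i, j],
                    "m": self.m[i, j], "s": self.s[i, j], "v": self.v[i, j],
                    "defined": bool(self.defined[i, j]),
                })
        return pd.DataFrame(rows)


def k2p_matrix(alignment: Alignment, metric: str = "k2p") -> DistanceMatrix:
    """All-pairs distance matrix with per-pair site bookkeeping.

    metric
        "k2p" (default) or "p" for the uncorrected proportion of
        differing sites (s + v) / m.
    """
    if metric not in ("k2p", "p"):
        raise ValueError(f"unknown metric {metric!r}")
    mat = alignment.matrix()
    n = len(alignment)
    determinate = mat < 4
    purine = (mat == 0) | (mat == 2)
    d = np.zeros((n, n))
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    m_arr = np.zeros((n, n), dtype=int)
    s_arr = np.zeros((n, n), dtype=int)
    v_arr = np.zeros((n, n), dtype=int)
    defined = np.ones((n, n), dtype=bool)
    for i in range(n):
        ok = determinate[i] & determinate[i + 1:]
        diff = ok & (mat[i] != mat[i + 1:])
        ts = (diff & (purine[i] == purine[i + 1:])).sum(axis=1)
        tot = diff.sum(axis=1)
        m_row = ok.sum(axis=1)
        for off, (mm, ss, dd) in enumerate(zip(m_row, ts, tot)):
            j = i + 1 + off
            m_arr[i, j] = mm
            s_arr[i, j] = ss
            v_arr[i, j] = dd - ss
            if mm == 0:
                defined[i, j] = False
                d[i, j] = P[i, j] = Q[i, j] = np.nan
                logger.warning("pair (%s, %s): no overlapping sites",
                               alignment.ids[i], alignment.ids[j])
                continue
            if metric == "p":
                d[i, j] = dd / mm
                P[i, j], Q[i, j] = ss / mm, (dd - ss) / mm
            else:
                dist, p_, q_, sat = _k2p_from_counts(mm, int(ss), int(dd - ss))
                d[i, j], P[i, j], Q[i, j] = dist, p_, q_
                if sat:
                    defined[i, j] = False
                    logger.warning("pair (%s, %s): saturated (P=%.3f, Q=%.3f)",
                                   alignment.ids[i], alignment.ids[j], p_, q_)
    for a in (d, P, Q):
        a += a.T
    for a in (m_arr, s_arr, v_arr):
        a += a.T
    defined &= defined.T
    np.fill_diagonal(defined, True)
    np.fill_diagonal(m_arr, alignment.length)
    return DistanceMatrix(list(alignment.ids), d, P, Q, m_arr, s_arr, v_arr,
                          defined)


def threshold_clusters(dm: DistanceMatrix, cutoff: float = 0.01,
                       linkage: str = "single") -> list[list[str]]:
    """Cluster ids at a distance threshold (99% similarity by default).

    Single linkage (default) takes connected components of the graph with
    an edge wherever d <= cutoff; complete linkage requires every within-
    cluster pair to satisfy d <= cutoff (agglomerative, scipy). Saturated
    or undefined pairs are treated as infinitely distant. Clusters are
    numbered by first-seen id, so the output order is deterministic.
    """
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must be in (0, 1)")
    n = len(dm.ids)
    dist = np.where(dm.defined, dm.d, np.inf)
    np.fill_diagonal(dist, 0.0)
    if not dm.defined.all():
        logger.warning("%d undefined pairs excluded from clustering",
                       int((~dm.defined).sum()) // 2)
    if linkage == "single":
        adj = dist <= cutoff
        _, labels = connected_components(csr_matrix(adj), directed=False)
    elif linkage == "complete":
        from scipy.cluster.hierarchy import complete, fcluster
        from scipy.spatial.distance import squareform
        finite_cap = np.nanmax(np.where(np.isfinite(dist), dist, 0.0)) + 1.0
        condensed = squareform(np.where(np.isfinite(dist), dist, finite_cap + cutoff),
                               checks=False)
        labels = fcluster(complete(condensed), t=cutoff, criterion="distance")
    else:
        raise ValueError(f"unknown linkage {linkage!r}")
    clusters: dict[int, list[str]] = {}
    order: list[int] = []
    for i in range(n):
        lab = int(labels[i])
        if lab not in clusters:
            clusters[lab] = []
            order.append(lab)
        clusters[lab].append(dm.ids[i])
    return [clusters[lab] for lab in order]


def clusters_to_dataframe(clusters: list[list[str]]) -> pd.DataFrame:
    rows = [{"id": member, "cluster": ci}
            for ci, members in enumerate(clusters) for member in members]
    return pd.DataFrame(rows)


def saturation_profile(alignment: Alignment) -> pd.DataFrame:
    """Per-pair transitions, transversions and K2P distance.

    Suitable for plotting s and v against d to inspect saturation; no
    test statistic is computed. Pairs without overlap are kept as rows
    flagged ``no_overlap``; saturated pairs are flagged ``saturated``.
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 sequences")
    dm = k2p_matrix(alignment)
    long = dm.to_long_dataframe()
    long["flag"] = ""
    long.loc[long["m"] == 0, "flag"] = "no_overlap"
    long.loc[(long["m"] > 0) & ~long["defined"], "flag"] = "saturated"
    return long[["id_a", "id_b", "s", "v", "d", "m", "flag"]]
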