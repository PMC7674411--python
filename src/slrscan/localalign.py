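"""Self-contained k-mer seed-and-extend local alignment.

Used for two jobs in the pipeline: (i) the cross-mapping diagnostic — does
the flanking sequence of a non-SLR sex-matched SNP match the Y haplotype? —
and (ii) decomposing a chimeric duplicate locus into progenitor segments by
maximum-score chaining of local hits.

Exact k-mer seeds are collected on both strands, extended ungapped with an
x-drop rule, then refined by a bounded-window local dynamic program (linear
gap cost) when the ungapped hit contains mismatches.  N bases never seed and
always score as mismatch.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ENC[_c] = _i
    _ENC[_c + 32] = _i
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class LocalAlignment:
    """One local hit; intervals 0-based half-open on the forward sequences.

    For strand '-', the reverse complement of ``query[qstart:qend]`` aligns
    to ``target[tstart:tend]``; the stored cigar is in that orientation
    (ops: M = aligned pair, I = gap in target, D = gap in query).
    """

    qstart: int
    qend: int
    tstart: int
    tend: int
    strand: str
    score: int
    n_matches: int
    aln_length: int
    cigar: list[tuple[str, int]] = field(default_factory=list)

    @property
    def identity(self) -> float:
        return self.n_matches / self.aln_length if self.aln_length else 0.0

    def __post_init__(self):
        if self.qend <= self.qstart or self.tend <= self.tstart:
            raise ValueError("alignment intervals must be non-empty")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


def recompute_identity(aln: LocalAlignment, query: str, target: str) -> float:
    """Re-derive identity from the emitted alignment (cigar + sequences)."""
    q = aln.qstart if aln.strand == "+" else None
    qseq = query[aln.qstart:aln.qend]
    if aln.strand == "-":
        qseq = revcomp(qseq)
    tseq = target[aln.tstart:aln.tend]
    qi = ti = matches = cols = 0
    for op, n in aln.cigar:
        if op == "M":
            for k in range(n):
                if qseq[qi + k] == tseq[ti + k] and qseq[qi + k] in "ACGT":
                    matches += 1
            qi += n
            ti += n
        elif op == "I":
            qi += n
        elif op == "D":
            ti += n
        cols += n
    return matches / cols if cols else 0.0


class KmerIndex:
    """Exact k-mer index of a target sequence (k-mers containing N skipped)."""

    def __init__(self, target: str, k: int = 13):
        if k < 4:
            raise ValueError("k must be >= 4")
        self.target = target
        self.k = k
        self.codes = _encode(target)
        self._index: dict[bytes, list[int]] = {}
        tb = target.upper().encode()
        bad = self.codes == 4
        # positions whose k-mer window contains an N
        has_n = np.convolve(bad.astype(np.int32), np.ones(k, dtype=np.int32),
                            mode="valid") > 0 if len(target) >= k else np.array([])
        for i in range(len(target) - k + 1):
            if has_n[i]:
                continue
            self._index.setdefault(tb[i:i + k], []).append(i)

    def lookup(self, kmer: bytes) -> list[int]:
        return self._index.get(kmer, [])


def smith_waterman(q: np.ndarray, t: np.ndarray, match: int = 1,
                   mismatch: int = -2, gap: int = -2):
    """Full local DP (linear gap), antidiagonal-vectorized.

    Returns (score, qstart, qend, tstart, tend, cigar, n_matches, length)
    for the best-scoring local alignment, or None when the optimum is 0.
    Coordinates are on the passed (already oriented) arrays.
    """
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    sub = np.where((q[:, None] == t[None, :]) & (q[:, None] < 4), match, mismatch)
    # row-wise with a running-max trick: for linear gaps,
    # H[i,j] = max_{k<=j} (max(0, diag_k, up_k) + (j-k)*gap)
    jg = np.arange(m + 1, dtype=np.int32) * gap
    B = np.empty(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        B[0] = 0
        np.maximum(H[i - 1, :-1] + sub[i - 1], H[i - 1, 1:] + gap, out=B[1:])
        np.maximum(B[1:], 0, out=B[1:])
        H[i] = np.maximum.accumulate(B - jg) + jg
    score = int(H.max())
    if score <= 0:
        return None
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    ops: list[str] = []
    matches = 0
    qe, te = i, j
    while H[i, j] > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub[i - 1, j - 1]:
            ops.append("M")
            if sub[i - 1, j - 1] == match:
                matches += 1
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            ops.append("I")
            i -= 1
        else:
            ops.append("D")
            j -= 1
    ops.reverse()
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return score, i, qe, j, te, cigar, matches, len(ops)


def _xdrop_ungapped(qc: np.ndarray, tc: np.ndarray, qpos: int, tpos: int,
                    k: int, match: int, mismatch: int, x_drop: int):
    """Extend an exact k-mer seed ungapped in both directions with x-drop."""

    def _ext(qarr, tarr):
        n = min(len(qarr), len(tarr))
        if n == 0:
            return 0, 0, 0
        eq = (qarr[:n] == tarr[:n]) & (qarr[:n] < 4)
        sc = np.where(eq, match, mismatch)
        cm = np.cumsum(sc)
        runmax = np.maximum.accumulate(cm)
        over = np.flatnonzero(runmax - cm > x_drop)
        cut = over[0] if over.size else n
        if cut == 0:
            return 0, 0, 0
        seg = cm[:cut]
        best = int(seg.argmax())
        if seg[best] <= 0:
            return 0, 0, 0
        ext = best + 1
        return ext, int(seg[best]), int(eq[:ext].sum())

    r_ext, r_sc, r_mt = _ext(qc[qpos + k:], tc[tpos + k:])
    l_ext, l_sc, l_mt = _ext(qc[:qpos][::-1], tc[:tpos][::-1])
    qs, qe = qpos - l_ext, qpos + k + r_ext
    ts, te = tpos - l_ext, tpos + k + r_ext
    score = l_sc + k * match + r_sc
    n_matches = l_mt + k + r_mt
    return qs, qe, ts, te, score, n_matches


def seed_extend_align(query: str, target: str | KmerIndex, k: int = 13,
                      min_len: int = 50, min_identity: float = 0.8,
                      match: int = 1, mismatch: int = -2, gap: int = -2,
                      x_drop: int = 40, refine: bool = True
                      ) -> list[LocalAlignment]:
    """Local alignments of query against both strands of target.

    Hits shorter than ``min_len`` alignment columns or below ``min_identity``
    are dropped; hits mostly covered by a better hit are suppressed.
    Deterministic.
    """
    index = target if isinstance(target, KmerIndex) else KmerIndex(target, k)
    if index.k != k:
        index = KmerIndex(index.target, k)
    k = index.k
    if k < 4:
        raise ValueError("k must be >= 4")
    tgt = index.target
    tc = index.codes
    hits: list[LocalAlignment] = []
    qlen = len(query)

    for strand in "+-":
        qseq = query.upper() if strand == "+" else revcomp(query.upper())
        qc = _encode(qseq)
        qb = qseq.encode()
        covered: dict[int, list[tuple[int, int]]] = {}
        for qpos in range(0, max(0, len(qseq) - k + 1)):
            kmer = qb[qpos:qpos + k]
            if b"N" in kmer:
                continue
            for tpos in index.lookup(kmer):
                diag = tpos - qpos
                spans = covered.get(diag)
                if spans and any(a <= qpos < b for (a, b) in spans):
                    continue
                qs, qe, ts, te, score, n_mt = _xdrop_ungapped(
                    qc, tc, qpos, tpos, k, match, mismatch, x_drop)
                covered.setdefault(diag, []).append((qs, qe))
                aln_len = qe - qs
                cigar = [("M", aln_len)]
                # refine when the hit has mismatches, or stops short of the
                # query ends (a perfect ungapped run truncated at an indel)
                if refine and (n_mt < aln_len or aln_len < len(qseq)):
                    # bounded-window gapped DP; if the refined alignment is
                    # clipped by the window, double the pad and redo.  An
                    # alignment ending near (not just at) the boundary is
                    # treated as clipped too: the window DP cannot see a
                    # score recovery past the edge, so it may stop a few
                    # columns short at a mismatch run it would otherwise
                    # cross.  The margin mirrors the deepest dip the
                    # extension is willing to bridge (x_drop / mismatch).
                    pad = x_drop + 10
                    edge = max(1, x_drop // max(1, -mismatch))
                    while True:
                        ws, we = max(0, qs - pad), min(len(qseq), qe + pad)
                        vs, ve = max(0, ts - pad), min(len(tgt), te + pad)
                        ref = smith_waterman(qc[ws:we], tc[vs:ve],
                                             match, mismatch, gap)
                        if ref is None or pad >= 2048:
                            break
                        clipped = ((ref[1] < edge and ws > 0)
                                   or (ref[2] > we - ws - edge
                                       and we < len(qseq))
                                   or (ref[3] < edge and vs > 0)
                                   or (ref[4] > ve - vs - edge
                                       and ve < len(tgt)))
                        if not clipped:
                            break
                        pad *= 2
                    if ref is not None and ref[0] > score:
                        score, rqs, rqe, rts, rte, cigar, n_mt, aln_len = ref
                        qs, qe, ts, te = ws + rqs, ws + rqe, vs + rts, vs + rte
                if aln_len < min_len or score <= 0:
                    continue
                if n_mt / aln_len < min_identity:
                    continue
                if strand == "+":
                    oqs, oqe = qs, qe
                else:
                    oqs, oqe = qlen - qe, qlen - qs
                hits.append(LocalAlignment(oqs, oqe, ts, te, strand,
                                           score, n_mt, aln_len, cigar))
    # suppress hits mostly contained in a better hit
    hits.sort(key=lambda h: (-h.score, h.qstart, h.tstart, h.strand))
    kept: list[LocalAlignment] = []
    for h in hits:
        redundant = False
        for g in kept:
            qov = min(h.qend, g.qend) - max(h.qstart, g.qstart)
            tov = min(h.tend, g.tend) - max(h.tstart, g.tstart)
            if (g.strand == h.strand
                    and qov > 0.9 * (h.qend - h.qstart)
                    and tov > 0.9 * (h.tend - h.tstart)):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def flag_crossmap_sems(sems_records, reference: Mapping[str, str],
                       slr_y_sequence: str, flank: int = 500,
                       min_identity: float = 0.9, k: int = 13,
                       min_len: int = 50, site_margin: int = 50):
    """Annotate non-SLR SEMS with a Y-haplotype similarity flag.

    For each record with ``in_slr`` False, the +/- ``flank`` window around
    the site on the discovery reference is aligned against the SLR-Y
    sequence; ``crossmap_suspect`` is True iff a hit with identity >=
    ``min_identity`` covers the site position or ends within ``site_margin``
    bp of it (the evidence is similarity of the *flanking* sequence: a
    local alignment is trimmed at terminal mismatches, and the suspect site
    is itself a mismatch against the Y copy, so a site at the edge of a
    Y-similar tract may sit just outside the maximal-scoring alignment).
    SLR records pass through unannotated.  Records are annotated in place
    and returned.

    Records whose flank windows overlap (sites closer than ``flank``) share
    one alignment pass over the merged window; the per-site coverage
    criterion is unchanged.
    """
    index = KmerIndex(slr_y_sequence, k)
    non_slr = [r for r in sems_records if not r.in_slr]
    for rec in sems_records:
        if rec.in_slr:
            rec.crossmap_suspect = None
    non_slr.sort(key=lambda r: (r.chrom, r.pos0))
    clusters: list[list] = []
    for rec in non_slr:
        if (clusters and clusters[-1][-1].chrom == rec.chrom
                and rec.pos0 - clusters[-1][-1].pos0 <= flank):
            clusters[-1].append(rec)
        else:
            clusters.append([rec])
    for group in clusters:
        seq = reference[group[0].chrom]
        ws = max(0, group[0].pos0 - flank)
        we = min(len(seq), group[-1].pos0 + flank + 1)
        hits = seed_extend_align(seq[ws:we], index, k=k, min_len=min_len,
                                 min_identity=min_identity)
        for rec in group:
            off = rec.pos0 - ws
            rec.crossmap_suspect = any(
                h.identity >= min_identity
                and h.qstart - site_margin <= off < h.qend + site_margin
                for h in hits)
    return sems_records


@dataclass
class ChimeraSegment:
    qstart: int
    qend: int
    source: str
    tstart: int
    tend: int
    strand: str
    identity: float
    score: int


@dataclass
class SegmentDecomposition:
    """Chained, non-overlapping decomposition of a chimera into source segments."""

    segments: list[ChimeraSegment]
    coverage_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.segments],
                            columns=["qstart", "qend", "source", "tstart",
                                     "tend", "strand", "identity", "score"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_json(self, path: str | Path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump({"coverage_fraction": self.coverage_fraction,
                       "segments": [s.__dict__ for s in self.segments]},
                      fh, sort_keys=True)


def chain_hits(hits: Sequence, max_overlap: int = 10, match: int = 1
               ) -> tuple[list[int], int]:
    """Maximum-score chain of hits, non-overlapping on the query up to
    ``max_overlap`` bp (overlap penalized at the match score).

    Source reuse and rearrangement are allowed — only query intervals
    constrain the chain.  Returns (selected indices in query order, value).
    O(n^2) dynamic program over hits sorted by query end.
    """
    order = sorted(range(len(hits)), key=lambda i: (hits[i].qend, hits[i].qstart))
    best = [0] * len(order)
    prev = [-1] * len(order)
    for a, i in enumerate(order):
        hi = hits[i]
        best[a] = hi.score
        for b, j in enumerate(order[:a]):
            hj = hits[j]
            ov = hj.qend - hi.qstart
            if ov > max_overlap or hj.qstart >= hi.qstart:
                continue
            val = best[b] + hi.score - max(0, ov) * match
            if val > best[a]:
                best[a] = val
                prev[a] = b
        # hits fully containing others could give qstart ties; handled above
    if not order:
        return [], 0
    a = int(np.argmax(best))
    value = best[a]
    chosen = []
    while a >= 0:
        chosen.append(order[a])
        a = prev[a]
    chosen.reverse()
    return chosen, int(value)


def decompose_chimeric(chimera: str, progenitors: Mapping[str, str],
                       min_len: int = 50, min_identity: float = 0.9,
                       k: int = 13, max_overlap: int = 10,
                       match: int = 1, mismatch: int = -2, gap: int = -2
                       ) -> SegmentDecomposition:
    """Decompose a chimeric duplicate into progenitor segments.

    All local hits of the chimera against each labeled progenitor are
    chained by weighted interval scheduling (repeats and rearrangements on
    the sources allowed); overlaps between consecutive chosen hits are
    resolved by realigning the downstream hit on its trimmed query interval.
    """
    if not progenitors:
        raise ValueError("at least one progenitor is required")
    scored = []
    for label, seq in progenitors.items():
        for h in seed_extend_align(chimera, seq, k=k, min_len=min_len,
                                   min_identity=min_identity,
                                   match=match, mismatch=mismatch, gap=gap):
            scored.append((label, h))
    if not scored:
        return SegmentDecomposition([], 0.0)
    chosen, _ = chain_hits([h for (_, h) in scored], max_overlap, match)
    picked = [scored[i] for i in chosen]
    picked.sort(key=lambda lh: lh[1].qstart)

    segments: list[ChimeraSegment] = []
    prev_end = 0
    for label, h in picked:
        qs, qe, ts, te, strand = h.qstart, h.qend, h.tstart, h.tend, h.strand
        score, n_mt, aln_len = h.score, h.n_matches, h.aln_length
        if qs < prev_end:  # trim the overlap off this hit's query start
            trimmed = _realign_trimmed(chimera, progenitors[label], h, prev_end,
                                       match, mismatch, gap)
            if trimmed is None:
                continue
            qs, qe, ts, te, score, n_mt, aln_len = trimmed
        if qe <= qs:
            continue
        segments.append(ChimeraSegment(qs, qe, label, ts, te, strand,
                                       n_mt / aln_len, score))
        prev_end = qe
    covered = sum(s.qend - s.qstart for s in segments)
    return SegmentDecomposition(segments, covered / len(chimera) if chimera else 0.0)


def _realign_trimmed(chimera: str, source: str, hit: LocalAlignment,
                     new_qstart: int, match: int, mismatch: int, gap: int):
    """Re-derive a hit after trimming its query interval to start at
    ``new_qstart``; returns (qs, qe, ts, te, score, matches, length) or None."""
    qs = max(hit.qstart, new_qstart)
    if hit.qend - qs < 1:
        return None
    sub = chimera[qs:hit.qend]
    if hit.strand == "-":
        sub = revcomp(sub)
    res = smith_waterman(_encode(sub), _encode(source[hit.tstart:hit.tend]),
                         match, mismatch, gap)
    if res is None:
        return None
    score, rqs, rqe, rts, rte, _cigar, n_mt, aln_len = res
    if hit.strand == "+":
        oqs, oqe = qs + rqs, qs + rqe
    else:
        oqs, oqe = qs + (len(sub) - rqe), qs + (len(sub) - rqs)
    return oqs, oqe, hit.tstart + rts, hit.tstart + rte, score, n_mt, aln_len


def write_alignments_tsv(alignments: Sequence[LocalAlignment], path: str | Path,
                         query_name: str = "query", target_name: str = "target"
                         ) -> None:
    """BLAST outfmt-6-like table (0-based half-open intervals)."""
    with open(path, "w") as fh:
        fh.write("query\tqstart\tqend\ttarget\ttstart\ttend\tstrand\tidentity\tscore\n")
        for a in alignments:
            fh.write(f"{query_name}\t{a.qstart}\t{a.qend}\t{target_name}\t"
                     f"{a.tstart}\t{a.tend}\t{a.strand}\t{a.identity:.4f}\t{a.score}\n")
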