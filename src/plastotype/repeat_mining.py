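"""SSR, dispersed-repeat and tandem-repeat mining for plastomes.

Thresholds follow the published plastome conventions:

* SSRs: perfect tandem arrays of 1-6 bp units with minimum copy numbers
  10/6/5/5/5/5 (MISA-style), reported at their smallest period with the
  motif standardised to its lexicographically minimal rotation.
* Dispersed repeats: direct (same strand) and palindromic (reverse
  complement) pairs >= 30 bp with Hamming distance <= 3 (no indels),
  i.e. identity >= 90% — the Vmatch-style "-l 30 -identity 90 -h 3" regime.
  Hits are inclusion-maximal windows per (anti)diagonal, trimmed to match
  endpoints.
* Tandem repeats: unit >= 7 bp, >= 1.9 copies, consensus match fraction
  >= 0.80 — a consensus-based simplification of the TRF "2 7 7 80 10 50 500"
  scoring, validated by planted-array recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import min_rotation, revcomp, smallest_period
from .errors import ContractError, ParameterError
from .records import GenomeInterval, PlastomeRecord
from .quadripartite import QuadripartitePartition

DEFAULT_SSR_THRESHOLDS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass
class SSRHit:
    motif: str
    unit_len: int
    copy_number: int
    interval: GenomeInterval
    region: str | None = None
    context: str | None = None

    def key(self):
        return (self.interval.start, self.unit_len)


@dataclass
class RepeatHit:
    kind: str                      # 'direct' | 'palindromic'
    interval_a: GenomeInterval
    interval_b: GenomeInterval
    length: int
    mismatches: int
    region_a: str | None = None
    region_b: str | None = None
    associated_genes: list[str] = field(default_factory=list)

    @property
    def identity(self) -> float:
        return (self.length - self.mismatches) / self.length


@dataclass
class TandemHit:
    unit: str
    copies: float
    interval: GenomeInterval
    match_fraction: float
    region: str | None = None
    context: str | None = None


# ---------------------------------------------------------------------------
# SSRs


def find_ssrs(sequence: str, thresholds: dict[int, int] | None = None) -> list[SSRHit]:
    """Maximal perfect SSR arrays above the per-unit-length copy thresholds.

    An array whose unit is itself periodic (ATAT as a 4-mer) is reported only
    at its smallest period. Runs containing N are broken at the N.
    """
    thr = DEFAULT_SSR_THRESHOLDS if thresholds is None else dict(thresholds)
    if not thr or any(
        not isinstance(u, int) or u < 1 or u > 6 or c < 2 for u, c in thr.items()
    ):
        raise ParameterError(f"invalid SSR threshold map: {thr}")
    s = sequence.upper()
    L = len(s)
    hits: list[SSRHit] = []
    for u in sorted(thr):
        i = u
        while i < L:
            if s[i] != s[i - u] or s[i] == "N":
                i += 1
                continue
            a = i
            while i < L and s[i] == s[i - u] and s[i] != "N":
                i += 1
            b = i  # maximal match run [a, b) at lag u
            total = (b - a) + u
            copies = total // u
            if copies >= thr[u]:
                unit = s[a - u : a]
                if "N" not in unit and smallest_period(unit) == u:
                    start = a - u
                    hits.append(
                        SSRHit(
                            motif=min_rotation(unit),
                            unit_len=u,
                            copy_number=copies,
                            interval=GenomeInterval(start, start + u * copies),
                        )
                    )
    hits.sort(key=lambda h: (h.interval.start, h.unit_len))
    return hits


# ---------------------------------------------------------------------------
# dispersed (direct / palindromic) repeats


def find_long_repeats(
    sequence: str,
    min_len: int = 30,
    max_mismatch: int = 3,
    exclude_ir_pair: bool = True,
    partition: QuadripartitePartition | None = None,
    record: PlastomeRecord | None = None,
    circular: bool = True,
    seed_k: int | None = None,
) -> list[RepeatHit]:
    """All maximal direct/palindromic repeat pairs under the Hamming regime.

    Hits are found by exact k-mer seeding (k chosen so every qualifying
    window must contain a seed) and per-diagonal enumeration of
    inclusion-maximal windows with <= ``max_mismatch`` mismatches, trimmed so
    both end columns match. When ``exclude_ir_pair`` and a partition are
    given, the IR arm self-match and any hit whose two intervals lie in
    opposite IR arms are removed.
    """
    if min_len <= 0:
        raise ParameterError("min_len must be positive")
    s = sequence.upper()
    L = len(s)
    if L < 2 * min_len:
        raise ContractError("sequence shorter than twice min_len")
    if seed_k is None:
        # pigeonhole: a window of min_len with max_mismatch mismatches
        # contains an exact run of at least ceil((min_len-mm)/(mm+1))
        seed_k = max(4, -(-(min_len - max_mismatch) // (max_mismatch + 1)))
    W = s + s if circular else s
    N = len(W)

    raw: list[tuple[str, int, int, int, int]] = []  # kind, diag, start, end, mm
    raw += _scan_direct(W, N, L, circular, seed_k, max_mismatch, min_len)
    raw += _scan_palindromic(W, N, L, circular, seed_k, max_mismatch, min_len)

    hits: list[RepeatHit] = []
    seen: set = set()
    for kind, off, ws, we, mm in raw:
        length = we - ws
        if kind == "direct":
            bs = ws + off
        else:
            bs = N - off - we
        a_start, b_start = ws % L if circular else ws, bs % L if circular else bs
        if circular and length > L:
            continue
        if not _disjoint(a_start, b_start, length, L if circular else N):
            continue
        lo_s, hi_s = sorted((a_start, b_start))
        key = (kind, lo_s, hi_s, length)
        if key in seen:
            continue
        seen.add(key)
        hits.append(
            RepeatHit(
                kind=kind,
                interval_a=_mk_interval(min(a_start, b_start), length, L if circular else N),
                interval_b=_mk_interval(max(a_start, b_start), length, L if circular else N),
                length=length,
                mismatches=mm,
            )
        )

    if exclude_ir_pair and partition is not None and not partition.ir_absent:
        hits = [h for h in hits if not _is_ir_arm_pair(h, partition)]
    if partition is not None:
        for h in hits:
            h.region_a = _collapse_ir(partition, h.interval_a)
            h.region_b = _collapse_ir(partition, h.interval_b)
    if record is not None:
        for h in hits:
            h.associated_genes = _overlapping_genes(record, (h.interval_a, h.interval_b))
    hits.sort(key=lambda h: (h.interval_a.start, -h.length, h.kind))
    return hits


def _mk_interval(start: int, length: int, L: int) -> GenomeInterval:
    end = start + length
    if end <= L:
        return GenomeInterval(start, end)
    return GenomeInterval(start, end - L, wraps=True)


def _disjoint(a: int, b: int, length: int, L: int) -> bool:
    if a == b:
        return False
    return (b - a) % L >= length and (a - b) % L >= length


def _scan_direct(W, N, L, circular, k, max_mm, min_len):
    index: dict[str, list[int]] = {}
    for p in range(N - k + 1):
        index.setdefault(W[p : p + k], []).append(p)
    out = []
    covered: dict[int, list[tuple[int, int]]] = {}
    for kmer, positions in index.items():
        if len(positions) < 2 or "N" in kmer:
            continue
        for ai in range(len(positions) - 1):
            for bi in range(ai + 1, len(positions)):
                p, q = positions[ai], positions[bi]
                d = q - p
                if d == 0 or (circular and d % L == 0):
                    continue
                if _covered(covered.get(d), p):
                    continue
                lo, hi = 0, N - d
                run, windows = _max_windows(
                    lambda x, d=d: W[x] == W[x + d] and W[x] != "N",
                    p, p + k, lo, hi, max_mm,
                )
                covered.setdefault(d, []).append(run)
                for ws, we, mm in windows:
                    if we - ws >= min_len:
                        out.append(("direct", d, ws, we, mm))
    return out


def _scan_palindromic(W, N, L, circular, k, max_mm, min_len):
    T = revcomp(W)
    index: dict[str, list[int]] = {}
    for p in range(N - k + 1):
        index.setdefault(T[p : p + k], []).append(p)
    out = []
    covered: dict[int, list[tuple[int, int]]] = {}
    for p in range(N - k + 1):
        kmer = W[p : p + k]
        if "N" in kmer:
            continue
        for q in index.get(kmer, ()):
            e = q - p
            if _covered(covered.get(e), p):
                continue
            lo, hi = max(0, -e), min(N, N - e)
            run, windows = _max_windows(
                lambda x, e=e: W[x] != "N" and W[x] == T[x + e],
                p, p + k, lo, hi, max_mm,
            )
            covered.setdefault(e, []).append(run)
            for ws, we, mm in windows:
                if we - ws >= min_len:
                    out.append(("palindromic", e, ws, we, mm))
    return out


def _covered(spans, p) -> bool:
    if not spans:
        return False
    return any(a <= p < b for a, b in spans)


def _max_windows(match, seed_lo, seed_hi, lo, hi, max_mm):
    """Inclusion-maximal windows with <= max_mm mismatches intersecting the
    exact-match run that contains the seed.

    The seed is first extended to its full exact run [rs, re); every maximal
    window intersecting that run is bounded by the (i+1)-th mismatch to the
    left and the (j+1)-th to the right of the run with i + j = max_mm, so
    collecting max_mm+1 mismatch positions per side enumerates them all.
    Returns (run, windows) where windows are (start, end, mismatches) tuples
    trimmed so the first and last columns are matches.
    """
    rs, re = seed_lo, seed_hi
    while rs - 1 >= lo and match(rs - 1):
        rs -= 1
    while re < hi and match(re):
        re += 1
    left = []  # mismatch positions left of the run, descending
    x = rs - 1
    while x >= lo and len(left) <= max_mm:
        if not match(x):
            left.append(x)
        x -= 1
    right = []  # mismatch positions right of the run, ascending
    x = re
    while x < hi and len(right) <= max_mm:
        if not match(x):
            right.append(x)
        x += 1
    lbounds = left + [lo - 1] * (max_mm + 1 - len(left))
    rbounds = right + [hi] * (max_mm + 1 - len(right))
    mism_set = set(left) | set(right)
    windows = set()
    for i in range(max_mm + 1):
        j = max_mm - i
        ws, we = max(lo, lbounds[i] + 1), min(hi, rbounds[j])
        while ws < we and ws in mism_set:
            ws += 1
        while we > ws and (we - 1) in mism_set:
            we -= 1
        if we <= ws:
            continue
        mm = sum(1 for m in mism_set if ws <= m < we)
        windows.add((ws, we, mm))
    return (rs, re), sorted(windows)


def _is_ir_arm_pair(hit: RepeatHit, part: QuadripartitePartition) -> bool:
    L = part.seq_len
    fa_irb = _overlap_fraction(hit.interval_a, part.irb, L)
    fa_ira = _overlap_fraction(hit.interval_a, part.ira, L)
    fb_irb = _overlap_fraction(hit.interval_b, part.irb, L)
    fb_ira = _overlap_fraction(hit.interval_b, part.ira, L)
    return (fa_irb >= 0.9 and fb_ira >= 0.9) or (fa_ira >= 0.9 and fb_irb >= 0.9)


def _overlap_fraction(iv: GenomeInterval, region: GenomeInterval, L: int) -> float:
    length = iv.length(L)
    if length == 0:
        return 0.0
    inside = sum(1 for o in range(length) if region.contains((iv.start + o) % L, L))
    return inside / length


def _collapse_ir(part: QuadripartitePartition, iv: GenomeInterval) -> str:
    region = part.region_of(iv.midpoint(part.seq_len)) if not part.ir_absent else "LSC"
    return "IR" if region in ("IRa", "IRb") else region


def _overlapping_genes(record: PlastomeRecord, intervals) -> list[str]:
    L = len(record)
    names = []
    for f in record.features:
        for exon in f.exons:
            if any(_intervals_overlap(exon, iv, L) for iv in intervals):
                names.append(f.name)
                break
    return sorted(set(names))


def _intervals_overlap(a: GenomeInterval, b: GenomeInterval, L: int) -> bool:
    la, lb = a.length(L), b.length(L)
    return (b.start - a.start) % L < la or (a.start - b.start) % L < lb


# ---------------------------------------------------------------------------
# tandem repeats


def find_tandem_repeats(
    sequence: str,
    min_unit: int = 7,
    max_unit: int = 100,
    min_copies: float = 1.9,
    min_match: float = 0.80,
) -> list[TandemHit]:
    """Detect tandem arrays with unit length >= ``min_unit``.

    Candidate periods come from lag-p autocorrelation; each candidate is
    refined against the majority consensus unit and accepted when the
    per-position match fraction vs the consensus stays >= ``min_match``.
    Reports at harmonic periods collapse onto the smallest period.
    """
    if min_unit < 2:
        raise ParameterError("min_unit must be >= 2")
    s = sequence.upper()
    L = len(s)
    if L < 2 * min_unit:
        raise ContractError("sequence shorter than twice min_unit")
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    hits: list[TandemHit] = []
    for p in range(min_unit, min(max_unit, L // 2) + 1):
        m = (arr[p:] == arr[:-p]) & (arr[p:] != ord("N"))
        if len(m) < p:
            continue
        # candidate anchors: length-p windows of the lag-p match profile with
        # enough agreement to suggest >= 2 aligned copies
        conv = np.convolve(m.astype(np.int32), np.ones(p, dtype=np.int32), "valid")
        cand = np.flatnonzero(conv >= 0.55 * p)
        if cand.size == 0:
            continue
        # group consecutive candidate offsets into segments; anchor each
        # segment at its autocorrelation maximum so rows are phase-aligned
        breaks = np.flatnonzero(np.diff(cand) > p)
        groups = np.split(cand, breaks + 1)
        for g in groups:
            anchor = int(g[np.argmax(conv[g])])
            hit = _refine_tandem(s, anchor, p, min_copies, min_match)
            if hit is not None and smallest_period(hit.unit) >= min_unit:
                hits.append(hit)
    hits = _dedupe_tandem(hits)
    hits.sort(key=lambda h: (h.interval.start, len(h.unit)))
    return hits


def _refine_tandem(s, anchor, p, min_copies, min_match):
    L = len(s)
    start = min(anchor, L - 2 * p)
    if start < 0:
        return None
    end = start + 2 * p

    def frac_vs(row, cons):
        return sum(a == b for a, b in zip(row, cons)) / p

    rows = [s[start : start + p], s[start + p : end]]
    consensus = _consensus(rows)
    # grow whole copies outward while they track the running consensus
    while start - p >= 0 and frac_vs(s[start - p : start], consensus) >= 0.7:
        start -= p
        rows.insert(0, s[start : start + p])
        consensus = _consensus(rows)
    while end + p <= L and frac_vs(s[end : end + p], consensus) >= 0.7:
        rows.append(s[end : end + p])
        end += p
        consensus = _consensus(rows)
    # trim edge copies that barely match the final consensus
    while rows and frac_vs(rows[0], consensus) < 0.7:
        rows = rows[1:]
        start += p
    while rows and frac_vs(rows[-1], consensus) < 0.7:
        rows = rows[:-1]
    if len(rows) < 2:
        return None
    end = start + len(rows) * p
    # partial-copy extension at both edges
    extra = 0
    while end + extra < L and extra < p and s[end + extra] == consensus[extra]:
        extra += 1
    end += extra
    lead = 0
    while start - lead - 1 >= 0 and lead < p and s[start - lead - 1] == consensus[p - 1 - lead]:
        lead += 1
    start -= lead
    total = end - start
    matches = sum(1 for o in range(total) if s[start + o] == consensus[(o - lead) % p])
    frac = matches / total
    copies = round(total / p, 2)
    if copies < min_copies or frac < min_match:
        return None
    return TandemHit(
        unit=consensus,
        copies=copies,
        interval=GenomeInterval(start, end),
        match_fraction=frac,
    )


def _consensus(rows: list[str]) -> str:
    return "".join(
        max(set(col), key=lambda c: (col.count(c), c)) for col in zip(*rows)
    )


def _dedupe_tandem(hits: list[TandemHit]) -> list[TandemHit]:
    """Collapse duplicate/harmonic reports, keeping the smallest period."""
    hits = sorted(hits, key=lambda h: (len(h.unit), -h.copies, h.interval.start))
    kept: list[TandemHit] = []
    for h in hits:
        dup = False
        for k in kept:
            if len(h.unit) % len(k.unit) == 0 and _jaccard(h.interval, k.interval) > 0.5:
                dup = True
                break
            if len(h.unit) == len(k.unit) and _jaccard(h.interval, k.interval) > 0.5:
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept


def _jaccard(a: GenomeInterval, b: GenomeInterval) -> float:
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    inter = max(0, hi - lo)
    union = (a.end - a.start) + (b.end - b.start) - inter
    return inter / union if union else 0.0


# ---------------------------------------------------------------------------
# region / context labels


def assign_context(hits, partition: QuadripartitePartition, record: PlastomeRecord):
    """Label each hit with its region (LSC/SSC/IR) and sequence context
    (CDS/intron/IGS/other) from the midpoint of its interval(s)."""
    if partition.seq_len and partition.seq_len != len(record):
        raise ContractError("partition and record describe different sequences")
    L = len(record)
    degenerate = partition.ir_absent
    for h in hits:
        if isinstance(h, RepeatHit):
            h.region_a = "LSC" if degenerate else _collapse_ir(partition, h.interval_a)
            h.region_b = "LSC" if degenerate else _collapse_ir(partition, h.interval_b)
            if not h.associated_genes:
                h.associated_genes = _overlapping_genes(record, (h.interval_a, h.interval_b))
        else:
            h.region = "LSC" if degenerate else _collapse_ir(partition, h.interval)
            h.context = _context_of(record, h.interval.midpoint(L))
    return hits


def _context_of(record: PlastomeRecord, pos: int) -> str:
    L = len(record)
    in_feature = False
    for f in record.features:
        exonic = any(e.contains(pos, L) for e in f.exons)
        if exonic:
            if f.category == "protein-coding" and not f.pseudo:
                return "CDS"
            in_feature = True
        elif len(f.exons) > 1 and _feature_span_contains(f, pos, L):
            return "intron"
    return "other" if in_feature else "IGS"


def _feature_span_contains(f, pos: int, L: int) -> bool:
    s = f.span_start()
    total = f.total_length(L)
    # conservative: span from first exon start to last exon end
    last_end = max((e.start + e.length(L)) for e in f.exons)
    return s <= pos < last_end if last_end <= L else GenomeInterval(s, last_end % L, wraps=True).contains(pos, L)
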