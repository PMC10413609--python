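"""Inverted-repeat detection and quadripartite (LSC/IRb/SSC/IRa) partitioning.

The canonical land-plant plastome carries two near-identical inverted-repeat
arms (IRa, IRb) separating a large and a small single-copy region. The four
junctions are named JLB (LSC|IRb), JSB (IRb|SSC), JSA (SSC|IRa) and
JLA (IRa|LSC). Genomes that have lost the IR (Cassytha-like) get a
degenerate partition with ``ir_absent=True``.

Detection seeds exact k-mer matches between the doubled sequence and the
reverse complement, groups seeds on anti-diagonals, and extends the maximal
arm pair outward with a small mismatch allowance. Circularity is handled by
the doubled sequence, so origin-spanning arms need no special casing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import revcomp
from .errors import ContractError, ParameterError
from .records import GenomeInterval, PlastomeRecord

JUNCTIONS = ("JLB", "JSB", "JSA", "JLA")


@dataclass
class QuadripartitePartition:
    """LSC/IRb/SSC/IRa intervals plus the four junction offsets."""

    lsc: GenomeInterval | None
    irb: GenomeInterval | None
    ssc: GenomeInterval | None
    ira: GenomeInterval | None
    junctions: dict[str, int] = field(default_factory=dict)
    ir_absent: bool = False
    ir_identity: float = 0.0
    ir_length: int = 0
    seq_len: int = 0

    def region_of(self, pos: int) -> str:
        """Region label of a genomic offset ('LSC', 'IRb', 'SSC', 'IRa')."""
        if self.ir_absent:
            return "LSC"
        for name, iv in (("LSC", self.lsc), ("IRb", self.irb), ("SSC", self.ssc), ("IRa", self.ira)):
            if iv is not None and iv.contains(pos, self.seq_len):
                return name
        raise ContractError(f"offset {pos} not covered by partition")  # pragma: no cover

    def intervals(self) -> dict[str, GenomeInterval]:
        out = {}
        for name, iv in (("LSC", self.lsc), ("IRb", self.irb), ("SSC", self.ssc), ("IRa", self.ira)):
            if iv is not None:
                out[name] = iv
        return out


@dataclass(frozen=True)
class ArmPair:
    """A candidate inverted-repeat arm pair (arm1.start <= arm2.start)."""

    arm1: GenomeInterval
    arm2: GenomeInterval
    mismatches: int
    identity: float
    length: int


def _arm_interval(start: int, end: int, L: int) -> GenomeInterval:
    """Normalise a [start, end) span on the doubled sequence to mod-L."""
    s = start % L
    e = end - start + s
    if e <= L:
        return GenomeInterval(s, e)
    return GenomeInterval(s, e - L, wraps=True)


def find_inverted_repeat(
    sequence: str,
    min_len: int = 1000,
    min_identity: float = 0.995,
    seed_k: int = 25,
) -> ArmPair | None:
    """Locate the maximal inverted-repeat arm pair of a circular sequence.

    Returns ``None`` when no disjoint pair of reverse-complementary arms of
    length >= ``min_len`` at identity >= ``min_identity`` exists. Ties on
    length break toward the smallest start offset.
    """
    if min_len < seed_k:
        raise ParameterError(f"min_len ({min_len}) must be >= seed_k ({seed_k})")
    L = len(sequence)
    if L < 2 * min_len:
        return None
    rc = revcomp(sequence)
    index: dict[str, list[int]] = {}
    for j in range(L - seed_k + 1):
        index.setdefault(rc[j : j + seed_k], []).append(j)
    D = sequence + sequence
    # group seeds on the anti-diagonal d = i + p2 (constant along an arm pair)
    diagonals: dict[int, list[int]] = {}
    for i in range(L):
        for j in index.get(D[i : i + seed_k], ()):
            p2 = L - j - seed_k  # forward-strand start of the rc-matching k-mer
            diagonals.setdefault(i + p2, []).append(i)

    best: ArmPair | None = None
    max_arm = L // 2
    seen: set[tuple[int, int]] = set()
    for d, seeds in sorted(diagonals.items()):
        # an anti-diagonal carries two mirror-image seed clusters (one per
        # arm); split on large gaps and extend each cluster independently
        seeds.sort()
        clusters: list[list[int]] = [[seeds[0]]]
        for i in seeds[1:]:
            if i - clusters[-1][-1] <= 2 * seed_k:
                clusters[-1].append(i)
            else:
                clusters.append([i])
        for cl in clusters:
            pair = _extend_pair(D, L, d, cl[0], cl[-1] + seed_k, min_identity,
                                max_arm, seed_k)
            if pair is None or pair.length < min_len:
                continue
            key = (pair.arm1.start, pair.arm2.start)
            if key in seen:
                continue
            seen.add(key)
            if best is None or (pair.length, -pair.arm1.start) > (
                best.length, -best.arm1.start
            ):
                best = pair
    return best


def _extend_pair(D: str, L: int, d: int, sa: int, ea: int,
                 min_identity: float, max_arm: int, seed_k: int):
    """Extend candidate armA=[sa,ea) whose mate mirrors across anti-diagonal d.

    Per-base pairing: position x pairs with y = d + seed_k - 1 - x, and a pair
    matches when D[x] is the complement of D[y]. Extension is greedy on exact
    matches; short interior mismatch runs (arm asymmetries of real records)
    are absorbed only when followed by a solidly matching stretch, so exact
    planted arms are recovered with exact endpoints.
    """
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    b0 = d + seed_k - 1
    N2 = 2 * L

    def match(x: int) -> bool:
        y = b0 - x
        if x < 0 or x >= N2 or y < 0 or y >= N2:
            return False
        a = D[x]
        return a in comp and comp[a] == D[y]

    lo, hi = sa, ea
    while lo < hi and not match(lo):
        lo += 1
    while hi > lo and not match(hi - 1):
        hi -= 1
    if hi - lo < seed_k:
        return None
    mismatches = sum(0 if match(x) else 1 for x in range(lo, hi))

    def budget(length: int) -> int:
        return int((1.0 - min_identity) * length)

    max_run = 3       # longest absorbable mismatch run
    confirm = 10      # window that must re-establish homology
    confirm_min = 8

    def extend(side: int, lo: int, hi: int, mm: int):
        while True:
            x = lo - 1 if side == 0 else hi
            if hi - lo >= max_arm:
                return lo, hi, mm
            if match(x):
                if side == 0:
                    lo -= 1
                else:
                    hi += 1
                continue
            # probe a mismatch run
            run = 0
            while run <= max_run and not match(x - run if side == 0 else x + run):
                run += 1
            if run > max_run:
                return lo, hi, mm
            probe = [x - run - t if side == 0 else x + run + t for t in range(confirm)]
            good = sum(1 for p in probe if match(p))
            if good < confirm_min or mm + run > budget(hi - lo + run + confirm):
                return lo, hi, mm
            mm += run
            if side == 0:
                lo = x - run
            else:
                hi = x + run + 1
    lo, hi, mismatches = extend(0, lo, hi, mismatches)
    lo, hi, mismatches = extend(1, lo, hi, mismatches)

    length = hi - lo
    if length < seed_k:
        return None
    a1 = _arm_interval(lo, hi, L)
    a2 = _arm_interval(b0 - hi + 1, b0 - lo + 1, L)
    if a1.start > a2.start:
        a1, a2 = a2, a1
    if _arms_overlap(a1, a2, L):
        return None
    identity = 1.0 - mismatches / length
    if identity < min_identity:
        return None
    return ArmPair(arm1=a1, arm2=a2, mismatches=mismatches, identity=identity,
                   length=length)


def _arms_overlap(a: GenomeInterval, b: GenomeInterval, L: int) -> bool:
    pts = (a.start, (a.start + a.length(L) - 1) % L)
    return any(b.contains(p, L) for p in pts) or any(a.contains(p, L) for p in (b.start, (b.start + b.length(L) - 1) % L))


def partition(record: PlastomeRecord, min_len: int = 1000, min_identity: float = 0.995,
              seed_k: int = 25) -> QuadripartitePartition:
    """Partition a circular plastome into LSC, IRb, SSC and IRa.

    The longer inter-arm gap is the LSC; the arm first encountered walking
    forward from the LSC is IRb. Genomes without a detectable IR get
    ``ir_absent=True`` with the whole genome as a single degenerate LSC.
    """
    if not record.circular:
        raise ContractError("partition requires a circular record")
    L = len(record)
    pair = find_inverted_repeat(record.sequence, min_len=min_len,
                                min_identity=min_identity, seed_k=seed_k)
    if pair is None:
        return QuadripartitePartition(
            lsc=GenomeInterval(0, L), irb=None, ssc=None, ira=None,
            junctions={}, ir_absent=True, seq_len=L,
        )
    a1, a2 = pair.arm1, pair.arm2
    end1 = (a1.start + a1.length(L)) % L
    end2 = (a2.start + a2.length(L)) % L
    gap1 = _gap_interval(end1, a2.start, L)   # after arm1 → before arm2
    gap2 = _gap_interval(end2, a1.start, L)   # after arm2 → before arm1
    if gap1.length(L) >= gap2.length(L):
        lsc, ssc = gap1, gap2
        irb, ira = a2, a1       # LSC (after arm1) runs into arm2 first
    else:
        lsc, ssc = gap2, gap1
        irb, ira = a1, a2
    junctions = {
        "JLB": irb.start,
        "JSB": (irb.start + irb.length(L)) % L,
        "JSA": ira.start,
        "JLA": (ira.start + ira.length(L)) % L,
    }
    part = QuadripartitePartition(
        lsc=lsc, irb=irb, ssc=ssc, ira=ira, junctions=junctions,
        ir_absent=False, ir_identity=pair.identity,
        ir_length=(irb.length(L) + ira.length(L)) // 2, seq_len=L,
    )
    _assert_tiling(part, L)
    return part


def _gap_interval(start: int, end: int, L: int) -> GenomeInterval:
    start %= L
    end %= L
    if start < end:
        return GenomeInterval(start, end)
    return GenomeInterval(start, end, wraps=True)


def _assert_tiling(part: QuadripartitePartition, L: int) -> None:
    total = sum(iv.length(L) for iv in part.intervals().values())
    if total != L:
        raise ContractError(
            f"partition does not tile the circle: {total} != {L}"
        )


@dataclass
class JunctionGene:
    """A gene near (or straddling) a quadripartite junction."""

    junction: str
    gene: str
    side: str            # region on which the bulk of the gene lies
    distance: int        # 0 when straddling, else bp gap to the boundary
    straddles: bool
    bp_before: int       # bases on the lower-coordinate side of the junction
    bp_after: int


def junction_genes(record: PlastomeRecord, part: QuadripartitePartition,
                   window: int = 1000) -> dict[str, list[JunctionGene]]:
    """Genes overlapping or within ``window`` bp of each junction.

    Straddling genes are reported with the bp apportioned to each side.
    """
    if part.ir_absent:
        raise ContractError("junction report undefined for an IR-absent partition")
    L = len(record)
    report: dict[str, list[JunctionGene]] = {j: [] for j in JUNCTIONS}
    for jname in JUNCTIONS:
        j = part.junctions[jname]
        for f in record.features:
            s = f.span_start()
            length = f.total_length(L) if len(f.exons) > 1 else f.exons[0].length(L)
            iv = f.exons[0] if len(f.exons) == 1 else GenomeInterval(s, (s + length) % L, wraps=s + length > L)
            # circular distance from the feature to the junction point
            straddles = _straddles(iv, j, L)
            if straddles:
                before = (j - iv.start) % L
                after = iv.length(L) - before
                side = part.region_of(iv.midpoint(L))
                report[jname].append(JunctionGene(jname, f.name, side, 0, True, before, after))
                continue
            d_start = (iv.start - j) % L
            iv_end = (iv.start + iv.length(L)) % L
            d_end = (j - iv_end) % L
            dist = min(d_start, d_end)
            if window > 0 and dist < window:
                side = part.region_of(iv.midpoint(L))
                report[jname].append(JunctionGene(jname, f.name, side, dist, False, 0, 0))
    return report


def _straddles(iv: GenomeInterval, j: int, L: int) -> bool:
    """True when the boundary point j falls strictly inside the interval."""
    off = (j - iv.start) % L
    return 0 < off < iv.length(L)
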