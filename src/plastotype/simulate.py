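"""Miniature synthetic plastomes of all six structural types, with ground truth.

The generator emits ~30 kb circular genomes (default LSC 18 kb, SSC 4 kb,
IR 4 kb per arm — a 1:5 scale model of a real ~150 kb plastome) carrying the
canonical junction gene order: the LSC ends in rps19, each IR arm carries
rpl2-rpl23-trnI-CAU-ycf2 (mirrored in the opposite arm), and the SSC carries
ndhF-rpl32-trnL-UAG-ccsA-ndhD-ycf1. Marker coding genes are intact synthetic
ORFs (start codon, no internal stop, terminal stop, plastid/bacterial code).
Intergenic spacers are random sequence at the target GC and are re-sampled
until free of SSR arrays, so every repeat present is a planted one.

Structural types are derived from the Type-I template by boundary
contraction (II, III), SSC insertion of trnI-CAU (IV) and of a pseudogenised
rpl23 (V), or whole-arm loss (VI). Arm boundaries get four forced mismatch
positions on each flank so that recovered IR endpoints are exactly the
planted ones.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

from ._util import revcomp
from .errors import CapacityError, ContractError, ParameterError
from .records import GeneFeature, GenomeInterval, PlastomeRecord
from .repeat_mining import find_ssrs

PLASTOME_TYPES = ("I", "II", "III", "IV", "V", "VI")

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS]

# gene complement of the miniature template: (name, category, length)
_GENE_LEN = {
    "trnH-GUG": 74, "psbA": 600, "matK": 900, "atpF": 450, "clpP1": 420,
    "rbcL": 600, "rps19": 279,
    "rpl2": 450, "rpl23": 282, "trnI-CAU": 74, "ycf2": 1200,
    "ndhF": 600, "rpl32": 180, "trnL-UAG": 80, "ccsA": 750, "ndhD": 900,
    "ycf1": 840,
}
# rpl23 codons one substitution away from TAA, used for pseudogenisation
_RPL23_STOPABLE = {20: "CAA", 60: "TAT"}


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic plastome."""

    seed: int = 0
    lsc_len: int = 18000
    ssc_len: int = 4000
    ir_len: int = 4000
    gc_target: float = 0.39
    type: str = "I"
    planted_ssrs: list = field(default_factory=list)      # (motif, copies, region)
    planted_repeats: list = field(default_factory=list)   # (length, kind, (region_a, region_b))
    substitution_rate: float = 0.0
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise ParameterError("region lengths must be positive")
        if self.type not in PLASTOME_TYPES:
            raise ParameterError(f"unknown plastome type {self.type}")
        for r in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= r <= 0.5:
                raise ParameterError("rates must lie in [0, 0.5]")


@dataclass
class Spacer:
    start: int
    end: int
    region: str
    tag: str | None = None
    plantable: bool = True


@dataclass
class MarkerTruth:
    name: str
    start: int
    end: int
    region: str
    pseudo: bool = False


@dataclass
class GroundTruth:
    """The generator's record of everything it planted."""

    seed: int
    type: str
    ir_absent: bool
    regions: dict[str, tuple[int, int]]
    markers: list[MarkerTruth]
    spacers: list[Spacer]
    marker_templates: dict[str, str]
    planted_ssrs: list[dict] = field(default_factory=list)
    planted_repeats: list[dict] = field(default_factory=list)
    mutations: list[int] = field(default_factory=list)
    indels: list[dict] = field(default_factory=list)

    def region_of(self, pos: int) -> str:
        for name, (s, e) in self.regions.items():
            if s <= pos < e:
                return name
        raise ContractError(f"position {pos} outside all regions")

    def marker_copies(self, name: str) -> list[MarkerTruth]:
        return [m for m in self.markers if m.name == name]

    def spacer_tagged(self, tag: str) -> Spacer:
        for sp in self.spacers:
            if sp.tag == tag:
                return sp
        raise ContractError(f"no spacer tagged {tag}")


def verify_truth(record: PlastomeRecord, truth: GroundTruth) -> None:
    """Check that planted coordinates re-extract to the planted strings."""
    s = record.sequence
    for p in truth.planted_ssrs:
        if s[p["start"] : p["end"]] != p["array"]:
            raise ContractError(f"planted SSR at {p['start']} does not re-extract")
    for r in truth.planted_repeats:
        a = s[r["a_start"] : r["a_start"] + r["length"]]
        b = s[r["b_start"] : r["b_start"] + r["length"]]
        want = a if r["kind"] == "direct" else revcomp(a)
        if b != want:
            raise ContractError(f"planted repeat at {r['a_start']} does not re-extract")
    for m in truth.markers:
        feats = [
            f for f in record.features_named(m.name) if f.span_start() == m.start
        ]
        if not feats:
            raise ContractError(f"marker {m.name}@{m.start} has no matching feature")


# ---------------------------------------------------------------------------
# random building blocks


def _random_spacer(rng, gc: float, n: int, tries: int = 100) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    for _ in range(tries):
        seq = "".join(rng.choice(bases, size=n, p=p))
        if n < 10 or not find_ssrs(seq):
            return seq
    raise CapacityError("could not sample an SSR-free spacer")


def _orf(rng, n: int, force_codons: dict[int, str] | None = None,
         gc: float = 0.39) -> str:
    if n % 3 or n < 9:
        raise ParameterError("ORF length must be a multiple of 3, >= 9")
    ncod = n // 3
    # codon usage follows the genomic base composition so whole-genome GC
    # tracks gc_target (real plastomes are AT-rich in coding regions too)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    weights = np.array(
        [p["ACGT".index(c[0])] * p["ACGT".index(c[1])] * p["ACGT".index(c[2])]
         for c in _CODONS]
    )
    weights /= weights.sum()
    for _ in range(100):
        codons = ["ATG"] + list(rng.choice(_CODONS, size=ncod - 2, p=weights)) + ["TAA"]
        for idx, cod in (force_codons or {}).items():
            codons[idx] = cod
        seq = "".join(codons)
        if not find_ssrs(seq):
            return seq
    raise CapacityError("could not sample an SSR-free ORF")


def _gene_like(rng, gc: float, n: int) -> str:
    return _random_spacer(rng, gc, n)


# ---------------------------------------------------------------------------
# template assembly


class _Builder:
    def __init__(self, rng, gc: float):
        self.rng = rng
        self.gc = gc
        self.chunks: list[str] = []
        self.pos = 0
        self.features: list[GeneFeature] = []
        self.spacers: list[Spacer] = []

    def push(self, seq: str) -> int:
        start = self.pos
        self.chunks.append(seq)
        self.pos += len(seq)
        return start

    def spacer(self, n: int, region: str, tag: str | None = None, plantable: bool = True):
        if n <= 0:
            raise CapacityError(f"region {region} too small for its gene set")
        start = self.push(_random_spacer(self.rng, self.gc, n))
        self.spacers.append(Spacer(start, start + n, region, tag, plantable))

    def gene(self, name: str, seq: str, category: str, strand: str = "+",
             exon_lens: tuple[int, ...] | None = None,
             intron_lens: tuple[int, ...] = ()):
        if exon_lens is None:
            start = self.push(seq)
            exons = [GenomeInterval(start, start + len(seq), strand=strand)]
        else:
            exons = []
            off = 0
            for i, el in enumerate(exon_lens):
                start = self.push(seq[off : off + el])
                exons.append(GenomeInterval(start, start + el, strand=strand))
                off += el
                if i < len(intron_lens):
                    self.push(_random_spacer(self.rng, self.gc, intron_lens[i]))
        self.features.append(GeneFeature(name=name, category=category, exons=exons))

    def sequence(self) -> str:
        return "".join(self.chunks)


def build_template(spec: SyntheticSpec) -> tuple[PlastomeRecord, GroundTruth]:
    """Assemble the Type-I reference genome for ``spec`` with ground truth.

    Deterministic in ``spec.seed``: identical specs give identical bytes.
    The whole genome is re-sampled (bounded retries) if any accidental SSR
    array survives assembly.
    """
    for attempt in range(50):
        rng = np.random.default_rng([int(spec.seed) % (2**31), attempt, 11])
        record, truth = _assemble(spec, rng)
        _force_ir_boundaries(record, truth)
        if not find_ssrs(record.sequence):
            verify_truth(record, truth)
            return record, truth
    raise CapacityError("could not assemble an SSR-free template")


def _assemble(spec: SyntheticSpec, rng) -> tuple[PlastomeRecord, GroundTruth]:
    gc = spec.gc_target
    seqs = {}
    for name, n in _GENE_LEN.items():
        if name.startswith("trn"):
            seqs[name] = _gene_like(rng, gc, n)
        elif name == "rpl23":
            seqs[name] = _orf(rng, n, force_codons=_RPL23_STOPABLE, gc=gc)
        else:
            seqs[name] = _orf(rng, n, gc=gc)

    B = _Builder(rng, gc)
    # --- LSC ---------------------------------------------------------------
    lsc_genes_span = (
        _GENE_LEN["trnH-GUG"] + _GENE_LEN["psbA"] + _GENE_LEN["matK"]
        + (_GENE_LEN["atpF"] + 180) + (_GENE_LEN["clpP1"] + 300)
        + _GENE_LEN["rbcL"] + _GENE_LEN["rps19"]
    )
    rem = spec.lsc_len - lsc_genes_span - 4 * 100 - 80
    if rem < 400:
        raise CapacityError("LSC too small for its gene set")
    plant_a, plant_b = rem // 2, rem - rem // 2
    B.gene("trnH-GUG", seqs["trnH-GUG"], "tRNA")
    B.spacer(100, "LSC")
    B.gene("psbA", seqs["psbA"], "protein-coding")
    B.spacer(100, "LSC")
    B.gene("matK", seqs["matK"], "protein-coding")
    B.spacer(100, "LSC")
    B.gene("atpF", seqs["atpF"], "protein-coding", exon_lens=(150, 300), intron_lens=(180,))
    B.spacer(100, "LSC")
    B.gene("clpP1", seqs["clpP1"], "protein-coding", exon_lens=(120, 150, 150), intron_lens=(150, 150))
    B.spacer(plant_a, "LSC", tag="lsc_plant_a")
    B.gene("rbcL", seqs["rbcL"], "protein-coding")
    B.spacer(plant_b, "LSC", tag="lsc_plant_b")
    B.gene("rps19", seqs["rps19"], "protein-coding")
    B.spacer(80, "LSC", tag="lsc_tail")
    if B.pos != spec.lsc_len:
        raise CapacityError("LSC layout does not close")  # pragma: no cover

    # --- IRb ---------------------------------------------------------------
    irb_start = B.pos
    ir_used = 150 + 450 + 120 + 282 + 120 + 74 + 200 + 1200
    ir_tail = spec.ir_len - ir_used
    if ir_tail < 100:
        raise CapacityError("IR too small for its gene set")
    B.spacer(150, "IRb")
    B.gene("rpl2", seqs["rpl2"], "protein-coding")
    B.spacer(120, "IRb")
    B.gene("rpl23", seqs["rpl23"], "protein-coding")
    B.spacer(120, "IRb")
    B.gene("trnI-CAU", seqs["trnI-CAU"], "tRNA")
    B.spacer(200, "IRb")
    B.gene("ycf2", seqs["ycf2"], "protein-coding")
    B.spacer(ir_tail, "IRb")
    irb_end = B.pos

    # --- SSC ---------------------------------------------------------------
    ssc_tail = spec.ssc_len - (600 + 180 + 80 + 750 + 900 + 840) - (5 * 60 + 300)
    if ssc_tail < 20:
        raise CapacityError("SSC too small for its gene set")
    B.spacer(60, "SSC", tag="ssc_head")
    B.gene("ndhF", seqs["ndhF"], "protein-coding")
    B.spacer(60, "SSC")
    B.gene("rpl32", seqs["rpl32"], "protein-coding")
    B.spacer(60, "SSC")
    B.gene("trnL-UAG", seqs["trnL-UAG"], "tRNA")
    B.spacer(300, "SSC", tag="ssc_insertion_zone")
    B.gene("ccsA", seqs["ccsA"], "protein-coding")
    B.spacer(60, "SSC")
    B.gene("ndhD", seqs["ndhD"], "protein-coding")
    B.spacer(60, "SSC")
    B.gene("ycf1", seqs["ycf1"], "protein-coding")
    B.spacer(ssc_tail, "SSC", tag="ssc_tail")
    ssc_end = B.pos

    # --- IRa: exact reverse complement of IRb with mirrored features -------
    ira_start = B.pos
    irb_seq = B.sequence()[irb_start:irb_end]
    B.push(revcomp(irb_seq))
    m = irb_end - irb_start
    for f in [f for f in B.features if irb_start <= f.exons[0].start < irb_end]:
        s, e = f.exons[0].start, f.exons[0].end
        ns = ira_start + (irb_end - e)
        ne = ira_start + (irb_end - s)
        strand = "-" if f.strand == "+" else "+"
        B.features.append(
            GeneFeature(f.name, f.category, [GenomeInterval(ns, ne, strand=strand)])
        )
    for sp in [s for s in B.spacers if irb_start <= s.start < irb_end]:
        B.spacers.append(
            Spacer(ira_start + (irb_end - sp.end), ira_start + (irb_end - sp.start),
                   "IRa", None, plantable=False)
        )
    total = B.pos
    if total != spec.lsc_len + spec.ssc_len + 2 * spec.ir_len:
        raise CapacityError("genome layout does not close")  # pragma: no cover

    regions = {
        "LSC": (0, spec.lsc_len),
        "IRb": (irb_start, irb_end),
        "SSC": (irb_end, ssc_end),
        "IRa": (ira_start, total),
    }
    record = PlastomeRecord(
        identifier=f"SYNPT1S{int(spec.seed)}",
        organism="Synthetic plastome (type I template)",
        sequence=B.sequence(),
        circular=True,
        features=B.features,
    )
    markers = []
    for f in record.features:
        if f.name in ("trnI-CAU", "rpl23", "rpl2", "ycf2"):
            s = f.span_start()
            region = next(n for n, (a, b) in regions.items() if a <= s < b)
            markers.append(MarkerTruth(f.name, s, s + f.total_length(total), region))
    truth = GroundTruth(
        seed=int(spec.seed),
        type="I",
        ir_absent=False,
        regions=regions,
        markers=markers,
        spacers=B.spacers,
        marker_templates={k: seqs[k] for k in ("trnI-CAU", "rpl23", "rpl2", "ycf2")},
    )
    return record, truth


def _force_ir_boundaries(record: PlastomeRecord, truth: GroundTruth) -> None:
    """Force 4 mismatching base pairs just outside each arm boundary so the
    planted arms are the maximal inverted repeat, with exact endpoints.

    Positions are only modified when they fall inside a known spacer.
    """
    if truth.ir_absent:
        return
    seq = bytearray(record.sequence.encode())
    L = len(seq)
    a, b = truth.regions["IRb"]
    c, d = truth.regions["IRa"]
    comp = {65: 84, 84: 65, 67: 71, 71: 67}

    def in_spacer(pos: int) -> bool:
        return any(sp.start <= pos < sp.end for sp in truth.spacers)

    def force(pos_mod: int, pos_ref: int):
        """Make seq[pos_mod] differ from complement(seq[pos_ref])."""
        if not in_spacer(pos_mod % L):
            return
        bad = comp[seq[pos_ref % L]]
        if seq[pos_mod % L] == bad:
            for cand in (65, 67, 71, 84):
                if cand != bad:
                    seq[pos_mod % L] = cand
                    break

    for j in range(4):
        force(a - 1 - j, j)                    # JLB flank pairs with JLA flank
        force(b + j, c - 1 - j)                # JSB flank pairs with JSA flank
    record.sequence = seq.decode()


# ---------------------------------------------------------------------------
# record surgery (delete / insert with truth bookkeeping)


def _clip(s: int, e: int, ds: int, de: int):
    k = de - ds
    if e <= ds:
        return (s, e)
    if s >= de:
        return (s - k, e - k)
    if s >= ds and e <= de:
        return None
    if s < ds and e > de:
        return (s, e - k)
    if s < ds:
        return (s, ds)
    return (ds, e - k)


def _delete(record: PlastomeRecord, truth: GroundTruth, ds: int, de: int):
    record = _copy.deepcopy(record)
    truth = _copy.deepcopy(truth)
    record.sequence = record.sequence[:ds] + record.sequence[de:]
    feats = []
    for f in record.features:
        exons = []
        for ex in f.exons:
            c = _clip(ex.start, ex.end, ds, de)
            if c is not None:
                exons.append(GenomeInterval(c[0], c[1], strand=ex.strand))
        if exons:
            f.exons = exons
            feats.append(f)
    record.features = feats
    for name in list(truth.regions):
        c = _clip(*truth.regions[name], ds, de)
        if c is None:
            del truth.regions[name]
        else:
            truth.regions[name] = c
    spacers = []
    for sp in truth.spacers:
        c = _clip(sp.start, sp.end, ds, de)
        if c is not None:
            sp.start, sp.end = c
            spacers.append(sp)
    truth.spacers = spacers
    markers = []
    for mk in truth.markers:
        c = _clip(mk.start, mk.end, ds, de)
        if c is not None:
            mk.start, mk.end = c
            markers.append(mk)
    truth.markers = markers
    return record, truth


def _insert(record: PlastomeRecord, truth: GroundTruth, pos: int, seq: str,
            features: list[GeneFeature], free_spans: list[tuple[int, int]]):
    """Insert ``seq`` at ``pos``; feature/free-span coordinates are relative
    to the inserted block."""
    record = _copy.deepcopy(record)
    truth = _copy.deepcopy(truth)
    k = len(seq)
    record.sequence = record.sequence[:pos] + seq + record.sequence[pos:]

    def shift_iv(s, e):
        if s >= pos:
            return s + k, e + k
        if e > pos:
            return s, e + k
        return s, e

    for f in record.features:
        f.exons = [
            GenomeInterval(*shift_iv(ex.start, ex.end), strand=ex.strand)
            for ex in f.exons
        ]
    for name in list(truth.regions):
        truth.regions[name] = shift_iv(*truth.regions[name])
    new_spacers = []
    for sp in truth.spacers:
        if sp.start < pos < sp.end:
            right = Spacer(pos + k, sp.end + k, sp.region, None, sp.plantable)
            sp.end = pos
            new_spacers.extend([sp, right])
        else:
            sp.start, sp.end = shift_iv(sp.start, sp.end)
            new_spacers.append(sp)
    for mk in truth.markers:
        mk.start, mk.end = shift_iv(mk.start, mk.end)
    for s, e in free_spans:
        region = truth.region_of(pos) if truth.regions else "LSC"
        new_spacers.append(Spacer(pos + s, pos + e, region))
    truth.spacers = new_spacers
    for nf in features:
        nf = _copy.deepcopy(nf)
        nf.exons = [
            GenomeInterval(ex.start + pos, ex.end + pos, strand=ex.strand)
            for ex in nf.exons
        ]
        record.features.append(nf)
    return record, truth


def _relabel(truth: GroundTruth) -> None:
    for mk in truth.markers:
        mk.region = truth.region_of((mk.start + mk.end) // 2)
    for sp in truth.spacers:
        if sp.start < sp.end:
            sp.region = truth.region_of(sp.start)


# ---------------------------------------------------------------------------
# type transforms


def apply_type_transform(record: PlastomeRecord, truth: GroundTruth,
                         target_type: str) -> tuple[PlastomeRecord, GroundTruth]:
    """Derive a Type II-VI genome from a Type-I template.

    II/III contract an IR boundary: the first ``cut`` bases of IRb fall out
    of the repeat (their annotations survive, now in the LSC) and the
    mirrored span at the far end of IRa is deleted, keeping the shortened
    arms exactly complementary. IV/V insert genes between trnL-UAG and ccsA
    in the SSC; VI deletes one whole arm.
    """
    if target_type not in PLASTOME_TYPES:
        raise ParameterError(f"unknown target type {target_type}")
    if truth.type != "I":
        raise ContractError("type transforms start from a Type-I template")
    if target_type == "I":
        return _copy.deepcopy(record), _copy.deepcopy(truth)

    L = len(record)
    a, b = truth.regions["IRb"]
    c, d = truth.regions["IRa"]
    if d != L:
        raise ContractError("transforms expect the IRa to end at the origin")

    if target_type == "VI":
        rec2, tr2 = _delete(record, truth, c, d)
        tr2.ir_absent = True
        tr2.regions = {"LSC": (0, len(rec2))}
        tr2.type = "VI"
        _relabel(tr2)
        return rec2, tr2

    def contract(cut: int):
        rec2, tr2 = _delete(record, truth, L - cut, L)
        tr2.regions["LSC"] = (0, a + cut)
        tr2.regions["IRb"] = (a + cut, b)
        return rec2, tr2

    if target_type == "II":
        rpl2 = next(m for m in truth.markers if m.name == "rpl2" and m.region == "IRb")
        cut = (rpl2.end + 60) - a
        rec2, tr2 = contract(cut)
        tr2.type = "II"
    else:  # III, IV, V share the deep contraction
        ycf2 = next(m for m in truth.markers if m.name == "ycf2" and m.region == "IRb")
        cut = (ycf2.start - a) + int(0.6 * (ycf2.end - ycf2.start))
        rec2, tr2 = contract(cut)
        tr2.type = "III"

    _relabel(tr2)
    _force_ir_boundaries(rec2, tr2)

    if target_type in ("II", "III"):
        verify_truth(rec2, tr2)
        return rec2, tr2

    # --- IV: insert an intact trnI-CAU copy between trnL-UAG and ccsA ------
    rng = np.random.default_rng([truth.seed % (2**31), 101])
    zone = tr2.spacer_tagged("ssc_insertion_zone")
    pos = (zone.start + zone.end) // 2
    trni = tr2.marker_templates["trnI-CAU"]
    flank_l = _random_spacer(rng, 0.39, 60)
    flank_r = _random_spacer(rng, 0.39, 60)
    block = flank_l + trni + flank_r
    feat = GeneFeature("trnI-CAU", "tRNA", [GenomeInterval(60, 60 + len(trni), strand="+")])
    rec2, tr2 = _insert(rec2, tr2, pos, block, [feat],
                        free_spans=[(0, 60), (60 + len(trni), len(block))])
    tr2.markers.append(MarkerTruth("trnI-CAU", pos + 60, pos + 60 + len(trni), "SSC"))
    tr2.type = "IV"
    _relabel(tr2)
    _force_ir_boundaries(rec2, tr2)
    if target_type == "IV":
        verify_truth(rec2, tr2)
        return rec2, tr2

    # --- V: add a pseudogenised rpl23 (two internal stops) after the trnI --
    rng = np.random.default_rng([truth.seed % (2**31), 102])
    rpl23 = tr2.marker_templates["rpl23"]
    codons = [rpl23[i : i + 3] for i in range(0, len(rpl23), 3)]
    for idx in _RPL23_STOPABLE:
        codons[idx] = "TAA"
    pseudo_seq = "".join(codons)
    trni_ssc = next(m for m in tr2.markers if m.name == "trnI-CAU" and m.region == "SSC")
    pos = trni_ssc.end + 30
    flank_l = _random_spacer(rng, 0.39, 30)
    flank_r = _random_spacer(rng, 0.39, 30)
    block = flank_l + pseudo_seq + flank_r
    feat = GeneFeature("rpl23", "protein-coding",
                       [GenomeInterval(30, 30 + len(pseudo_seq), strand="+")], pseudo=True)
    rec2, tr2 = _insert(rec2, tr2, pos, block, [feat],
                        free_spans=[(0, 30), (30 + len(pseudo_seq), len(block))])
    tr2.markers.append(
        MarkerTruth("rpl23", pos + 30, pos + 30 + len(pseudo_seq), "SSC", pseudo=True)
    )
    tr2.type = "V"
    _relabel(tr2)
    _force_ir_boundaries(rec2, tr2)
    verify_truth(rec2, tr2)
    return rec2, tr2


# ---------------------------------------------------------------------------
# planting


def _allocate(truth: GroundTruth, region: str, size: int, margin: int = 6) -> int:
    cands = [
        sp for sp in truth.spacers
        if sp.plantable and sp.region == region and (sp.end - sp.start) >= size + 2 * margin
    ]
    if not cands:
        raise CapacityError(f"no spacer in {region} can hold {size} bp")
    sp = max(cands, key=lambda s: s.end - s.start)
    start = sp.start + margin
    sp.start = start + size + margin
    return start


def plant_repeats(record: PlastomeRecord, truth: GroundTruth,
                  ssrs=(), repeats=(), seed: int = 0):
    """Overwrite spacer sequence with SSR arrays and dispersed repeat pairs.

    SSRs are (motif, copies, region); repeats are (length, kind,
    (region_a, region_b)) with kind in {'direct', 'palindromic'} and regions
    in {'LSC', 'SSC'}. Guard bases around every planted element force the
    array/pair to be maximal at exactly the planted coordinates.
    """
    record = _copy.deepcopy(record)
    truth = _copy.deepcopy(truth)
    rng = np.random.default_rng([truth.seed % (2**31), 7, len(truth.planted_ssrs)])
    seq = bytearray(record.sequence.encode())

    def set_guard(pos: int, *avoid: int):
        for cand in b"ACGT":
            if cand not in avoid:
                seq[pos] = cand
                return

    for motif, copies, region in ssrs:
        motif = motif.upper()
        u = len(motif)
        if not 1 <= u <= 6 or copies < 2:
            raise ParameterError(f"bad SSR plant ({motif},{copies})")
        array = motif * copies
        start = _allocate(truth, region, len(array))
        seq[start : start + len(array)] = array.encode()
        set_guard(start - 1, ord(motif[(u - 1) % u]))
        set_guard(start + len(array), ord(motif[0]))
        truth.planted_ssrs.append(
            {"motif": motif, "copies": copies, "start": start,
             "end": start + len(array), "array": array, "region": region}
        )

    comp = {65: 84, 84: 65, 67: 71, 71: 67}
    for length, kind, (ra, rb) in repeats:
        if kind not in ("direct", "palindromic"):
            raise ParameterError(f"unknown repeat kind {kind}")
        core = _random_spacer(rng, 0.39, length)
        a_start = _allocate(truth, ra, length)
        b_start = _allocate(truth, rb, length)
        seq[a_start : a_start + length] = core.encode()
        mate = core if kind == "direct" else revcomp(core)
        seq[b_start : b_start + length] = mate.encode()
        for j in range(1, 5):
            if kind == "direct":
                set_guard(b_start - j, seq[a_start - j])
                set_guard(b_start + length - 1 + j, seq[a_start + length - 1 + j])
            else:
                # left of a pairs beyond the right end of b, and vice versa
                set_guard(b_start + length - 1 + j, comp[seq[a_start - j]])
                set_guard(b_start - j, comp[seq[a_start + length - 1 + j]])
        truth.planted_repeats.append(
            {"kind": kind, "a_start": a_start, "b_start": b_start, "length": length}
        )

    record.sequence = seq.decode()
    verify_truth(record, truth)
    return record, truth


def plant_trni_duplication(record: PlastomeRecord, truth: GroundTruth,
                           length: int = 153):
    """Extend the trnI-CAU duplication of a Type IV/V genome to ``length`` bp.

    Copies the window centred on the single-copy trnI-CAU (now in the LSC
    after IR contraction) over the flanks of the SSC-inserted copy, so the
    genome's longest dispersed repeat becomes a ``length`` bp direct repeat
    covering trnI-CAU — the scenario behind SSC expansion in the Ocotea
    group.
    """
    if truth.type not in ("IV", "V"):
        raise ContractError("requires a Type IV or V genome")
    record = _copy.deepcopy(record)
    truth = _copy.deepcopy(truth)
    lsc = next(m for m in truth.markers if m.name == "trnI-CAU" and m.region == "LSC")
    ssc = next(m for m in truth.markers if m.name == "trnI-CAU" and m.region == "SSC")
    glen = lsc.end - lsc.start
    if length <= glen:
        raise ParameterError("duplication must be longer than the gene")
    flank = (length - glen) // 2
    a_start = lsc.start - flank
    b_start = ssc.start - flank
    seq = bytearray(record.sequence.encode())
    window = bytes(seq[a_start : a_start + length])
    seq[b_start : b_start + length] = window
    for j in range(1, 5):
        for cand in b"ACGT":
            if cand != seq[a_start - j]:
                seq[b_start - j] = cand
                break
        for cand in b"ACGT":
            if cand != seq[a_start + length - 1 + j]:
                seq[b_start + length - 1 + j] = cand
                break
    record.sequence = seq.decode()
    _reserve(truth, b_start - 4, b_start + length + 4)
    _reserve(truth, a_start - 4, a_start + length + 4)
    truth.planted_repeats.append(
        {"kind": "direct", "a_start": a_start, "b_start": b_start, "length": length}
    )
    verify_truth(record, truth)
    return record, truth


def _reserve(truth: GroundTruth, start: int, end: int) -> None:
    out = []
    for sp in truth.spacers:
        c = _clip_reserve(sp, start, end)
        out.extend(c)
    truth.spacers = out


def _clip_reserve(sp: Spacer, start: int, end: int) -> list[Spacer]:
    if sp.end <= start or sp.start >= end:
        return [sp]
    parts = []
    if sp.start < start:
        parts.append(Spacer(sp.start, start, sp.region, sp.tag, sp.plantable))
    if sp.end > end:
        parts.append(Spacer(end, sp.end, sp.region, sp.tag, sp.plantable))
    return parts


# ---------------------------------------------------------------------------
# divergence simulation


def mutate(record: PlastomeRecord, truth: GroundTruth,
           substitution_rate: float = 0.0, indel_rate: float = 0.0,
           seed: int = 0) -> tuple[PlastomeRecord, GroundTruth]:
    """Per-site substitutions (and spacer indels) with IR arms kept mirrored.

    Substitutions sampled inside IRa are driven from IRb: a mutated IRb base
    is complemented at its mirror position so the arms stay exactly
    complementary. Indels (length 1-5, geometric) are placed in single-copy
    intergenic spacers so feature annotations stay valid. All changed
    positions are recorded in the returned truth.
    """
    for r in (substitution_rate, indel_rate):
        if not 0.0 <= r <= 0.5:
            raise ParameterError("rates must lie in [0, 0.5]")
    record = _copy.deepcopy(record)
    truth = _copy.deepcopy(truth)
    rng = np.random.default_rng([int(seed) % (2**31), 23])
    L = len(record)
    seq = bytearray(record.sequence.encode())
    comp = {65: 84, 84: 65, 67: 71, 71: 67}
    others = {base: [o for o in b"ACGT" if o != base] for base in b"ACGT"}

    arms = None
    if not truth.ir_absent and "IRb" in truth.regions and "IRa" in truth.regions:
        arms = (truth.regions["IRb"], truth.regions["IRa"])

    changed: list[int] = []
    if substitution_rate > 0:
        hits = np.flatnonzero(rng.random(L) < substitution_rate)
        for pos in hits.tolist():
            if arms and arms[1][0] <= pos < arms[1][1]:
                continue  # IRa follows its IRb master
            old = seq[pos]
            if old not in comp:
                continue
            seq[pos] = others[old][rng.integers(0, 3)]
            changed.append(pos)
            if arms and arms[0][0] <= pos < arms[0][1]:
                (a0, a1), (c0, c1) = arms
                mirror = c0 + ((a1 - a0) - 1 - (pos - a0))
                seq[mirror] = comp[seq[pos]]
                changed.append(mirror)

    record.sequence = seq.decode()
    truth.mutations = sorted(changed)

    if indel_rate > 0:
        n_indels = int(rng.binomial(L, indel_rate))
        for _ in range(n_indels):
            cands = [
                sp for sp in truth.spacers
                if sp.plantable and sp.region in ("LSC", "SSC") and sp.end - sp.start > 12
            ]
            if not cands:
                break
            sp = cands[int(rng.integers(0, len(cands)))]
            ln = int(min(rng.geometric(0.5), 5))
            pos = int(rng.integers(sp.start + 2, sp.end - 2 - ln))
            if rng.random() < 0.5:
                record, truth = _delete(record, truth, pos, pos + ln)
                truth.indels.append({"op": "del", "pos": pos, "len": ln})
            else:
                ins = _random_spacer(rng, 0.39, ln, tries=100) if ln >= 10 else "".join(
                    "ACGT"[int(rng.integers(0, 4))] for _ in range(ln)
                )
                record, truth = _insert(record, truth, pos, ins, [], [])
                truth.indels.append({"op": "ins", "pos": pos, "len": ln})
    return record, truth


# ---------------------------------------------------------------------------
# one-call convenience


def simulate(spec: SyntheticSpec) -> tuple[PlastomeRecord, GroundTruth]:
    """Template -> type transform -> planting -> divergence, per ``spec``."""
    record, truth = build_template(spec)
    if spec.type != "I":
        record, truth = apply_type_transform(record, truth, spec.type)
    if spec.planted_ssrs or spec.planted_repeats:
        record, truth = plant_repeats(
            record, truth, ssrs=spec.planted_ssrs, repeats=spec.planted_repeats,
            seed=spec.seed,
        )
    if spec.substitution_rate or spec.indel_rate:
        record, truth = mutate(
            record, truth, spec.substitution_rate, spec.indel_rate, seed=spec.seed
        )
    record.identifier = f"SYNPT{spec.type}S{spec.seed}"[:16]
    record.organism = f"Synthetic plastome (type {spec.type})"
    return record, truth
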