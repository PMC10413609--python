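"""Marker-gene profiling, pseudogene detection and plastome Type I-VI calls.

Lauraceae plastomes fall into six structural types defined by the copy
number and placement of three unstable genes (rpl2, rpl23, trnI-CAU), the
state of ycf2 at the IR boundary, insertions between trnL-UAG and ccsA in
the SSC, and IR presence:

* Type I   - rpl2, rpl23 and trnI-CAU duplicated in both IR arms (ancestral).
* Type II  - one rpl2 copy lost by IRb boundary contraction.
* Type III - rpl2, rpl23, trnI-CAU single-copy; one ycf2 truncated.
* Type IV  - Type III plus a second trnI-CAU inserted between trnL-UAG and
  ccsA in the SSC.
* Type V   - Type IV plus a pseudogenised rpl23 in the same SSC insertion.
* Type VI  - IR lost entirely (Cassytha-like).

Profiles that satisfy none of the rows surface as UNKNOWN with diagnostics
rather than being forced to the nearest type.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from ._util import revcomp
from .errors import ContractError
from .records import GenomeInterval, PlastomeRecord
from .quadripartite import QuadripartitePartition

MARKER_GENES = ("trnI-CAU", "rpl23", "rpl2")
YCF2_TRUNCATION_FRACTION = 0.80   # copies shorter than this fraction of the
                                  # longest copy count as truncated
PSEUDO_IDENTITY_GATE = 0.90       # homology gate for pseudogene calls
_START_CODONS = ("ATG", "GTG", "TTG")  # bacterial/plastid table 11


@dataclass
class MarkerCopy:
    region: str
    interval: GenomeInterval
    pseudo: bool


@dataclass
class Ycf2Copy:
    region: str
    length: int
    truncated: bool


@dataclass
class MarkerProfile:
    """Copy counts and placements of the diagnostic junction markers."""

    copies: dict[str, list[MarkerCopy]]
    ycf2_copies: list[Ycf2Copy]
    ssc_insertion: list[str]
    ssc_insertion_defined: bool
    ir_absent: bool

    def regions_of(self, gene: str) -> list[str]:
        return sorted(c.region for c in self.copies.get(gene, []))


@dataclass
class TypeCall:
    type: str
    evidence: list[str]
    profile: MarkerProfile


@dataclass
class PseudogeneCall:
    identity_to_reference: float
    internal_stop_count: int
    frameshift: bool
    is_pseudo: bool


def profile_markers(record: PlastomeRecord, part: QuadripartitePartition) -> MarkerProfile:
    """Locate every copy of the marker genes and measure the ycf2 copies.

    Each copy is assigned to the region containing its midpoint, so genes
    straddling a junction get a single unambiguous label. The SSC insertion
    is the ordered list of genes lying strictly between the trnL-UAG and
    ccsA anchors when walking the SSC forward.
    """
    L = len(record)
    copies: dict[str, list[MarkerCopy]] = {g: [] for g in MARKER_GENES}
    for gene in MARKER_GENES:
        for f in record.features_named(gene):
            region = "LSC" if part.ir_absent else part.region_of(f.midpoint(L))
            iv = f.exons[0]
            copies[gene].append(MarkerCopy(region=region, interval=iv, pseudo=f.pseudo))
    ycf2 = []
    lengths = [f.total_length(L) for f in record.features_named("ycf2")]
    longest = max(lengths, default=0)
    for f in record.features_named("ycf2"):
        ln = f.total_length(L)
        region = "LSC" if part.ir_absent else part.region_of(f.midpoint(L))
        ycf2.append(Ycf2Copy(region=region, length=ln, truncated=ln < YCF2_TRUNCATION_FRACTION * longest))

    insertion, defined = _ssc_insertion(record, part)
    return MarkerProfile(
        copies=copies,
        ycf2_copies=ycf2,
        ssc_insertion=insertion,
        ssc_insertion_defined=defined,
        ir_absent=part.ir_absent,
    )


def _ssc_insertion(record: PlastomeRecord, part: QuadripartitePartition):
    """Genes whose full extent lies between trnL-UAG (3' end) and ccsA (5'
    start) walking the SSC; undefined (flagged) when an anchor is missing."""
    anchors = {}
    L = len(record)
    for anchor in ("trnL-UAG", "ccsA"):
        feats = record.features_named(anchor)
        if not feats:
            return [], False
        anchors[anchor] = feats[0]
    lo = max(e.start + e.length(L) for e in anchors["trnL-UAG"].exons) % L
    hi = anchors["ccsA"].span_start()
    between = []
    for f in record.features:
        if f.name in ("trnL-UAG", "ccsA"):
            continue
        s = f.span_start()
        e = s + f.total_length(L)  # exclusive end; may exceed L for wrappers
        if _within(lo, hi, s, L) and _within(lo, hi, (e - 1) % L, L):
            between.append((s, f.name))
    between.sort()
    return [name for _, name in between], True


def _within(lo: int, hi: int, pos: int, L: int) -> bool:
    span = (hi - lo) % L
    return 0 <= (pos - lo) % L <= span


def detect_pseudogene(query: str, reference: str) -> PseudogeneCall:
    """Call a gene copy pseudo from identity, internal stops and frameshifts.

    The reference must be an intact coding sequence (start codon, single
    terminal stop, plastid/bacterial code). Inputs are auto-oriented: if the
    reference does not look like a coding-strand ORF both sequences are
    reverse-complemented, which makes the call strand-consistent.
    """
    if not query or not reference:
        raise ContractError("detect_pseudogene requires non-empty sequences")
    query, reference = query.upper(), reference.upper()
    if not _looks_like_orf(reference) and _looks_like_orf(revcomp(reference)):
        query, reference = revcomp(query), revcomp(reference)

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    aln = aligner.align(reference, query)[0]
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    identity = counts.identities / columns

    frameshift = any(g % 3 != 0 for g in _gap_runs(aln))

    prot = str(Seq(query[: len(query) - len(query) % 3]).translate(table=11))
    internal = prot[:-1] if prot.endswith("*") else prot
    internal_stop_count = internal.count("*")

    is_pseudo = identity >= PSEUDO_IDENTITY_GATE and (internal_stop_count >= 1 or frameshift)
    return PseudogeneCall(
        identity_to_reference=identity,
        internal_stop_count=internal_stop_count,
        frameshift=frameshift,
        is_pseudo=is_pseudo,
    )


def _looks_like_orf(seq: str) -> bool:
    if len(seq) < 6 or len(seq) % 3 != 0:
        return False
    prot = str(Seq(seq).translate(table=11))
    return seq[:3] in _START_CODONS and prot.endswith("*") and "*" not in prot[:-1]


def _gap_runs(aln) -> list[int]:
    """Lengths of indel runs in a Bio.Align alignment."""
    runs = []
    blocks_ref, blocks_qry = aln.aligned
    for k in range(1, len(blocks_ref)):
        runs.append(int(blocks_ref[k][0] - blocks_ref[k - 1][1]))
        runs.append(int(blocks_qry[k][0] - blocks_qry[k - 1][1]))
    return [r for r in runs if r > 0]


def classify_type(profile: MarkerProfile) -> TypeCall:
    """Assign a plastome structural type from a marker profile.

    The decision table is evaluated in order VI, I, II, III, IV, V; profiles
    matching no row return UNKNOWN with the rules they violated (never an
    exception). The call is a pure function of the profile.
    """
    ev: list[str] = []
    if profile.ir_absent:
        return TypeCall("VI", ["IR absent (Cassytha-like degenerate partition)"], profile)

    def count(gene):
        return len(profile.copies[gene])

    regions = {g: profile.regions_of(g) for g in MARKER_GENES}
    full_ycf2 = [c for c in profile.ycf2_copies if not c.truncated]
    trunc_ycf2 = [c for c in profile.ycf2_copies if c.truncated]
    ins = profile.ssc_insertion

    if all(regions[g] == ["IRa", "IRb"] for g in MARKER_GENES) and len(full_ycf2) >= 2:
        ev.append("trnI-CAU, rpl23, rpl2 each duplicated with one copy per IR arm")
        ev.append(f"{len(full_ycf2)} complete ycf2 copies")
        return TypeCall("I", ev, profile)

    if (
        count("rpl2") == 1
        and regions["rpl23"] == ["IRa", "IRb"]
        and regions["trnI-CAU"] == ["IRa", "IRb"]
    ):
        ev.append("rpl2 single-copy (IRb boundary contraction)")
        ev.append("trnI-CAU and rpl23 still duplicated in both arms")
        return TypeCall("II", ev, profile)

    singles = all(count(g) == 1 for g in MARKER_GENES)
    one_full_one_trunc = len(full_ycf2) == 1 and len(trunc_ycf2) == 1
    if singles and one_full_one_trunc and not ins:
        ev.append("trnI-CAU, rpl23, rpl2 all single-copy")
        ev.append("one complete and one truncated ycf2")
        return TypeCall("III", ev, profile)

    trni_in_ins = "trnI-CAU" in ins
    rpl23_in_ins = [c for c in profile.copies["rpl23"] if c.region == "SSC"]
    if (
        count("trnI-CAU") == 2
        and trni_in_ins
        and count("rpl2") == 1
        and one_full_one_trunc
    ):
        if count("rpl23") == 1 and "rpl23" not in ins:
            ev.append("second trnI-CAU inserted between trnL-UAG and ccsA in the SSC")
            ev.append("rpl2, rpl23 single-copy; one complete + one truncated ycf2")
            return TypeCall("IV", ev, profile)
        if rpl23_in_ins and any(c.pseudo for c in rpl23_in_ins) and "rpl23" in ins:
            ev.append("second trnI-CAU plus pseudogenised rpl23 in the SSC insertion")
            return TypeCall("V", ev, profile)

    ev.append("no decision row fired:")
    for g in MARKER_GENES:
        ev.append(f"  {g}: {count(g)} copies in {regions[g] or ['-']}")
    ev.append(f"  ycf2: {len(full_ycf2)} complete, {len(trunc_ycf2)} truncated")
    if not profile.ssc_insertion_defined:
        ev.append("  SSC insertion undefined (trnL-UAG or ccsA missing)")
    else:
        ev.append(f"  SSC insertion: {ins or 'empty'}")
    return TypeCall("UNKNOWN", ev, profile)
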