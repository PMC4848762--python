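"""Fused-barcode read counting and plate-index (RCP) demultiplexing.

Reads from the fused-barcode amplicon carry two 25-mers — the bait barcode
and the prey barcode — separated by a lox-derived spacer and flanked by
common priming-site anchors.  Matching is anchor location at fixed offsets
followed by bounded-Hamming lookup of each 25-mer against the design's
barcode dictionary; ambiguous hits (two dictionary entries tied at the
minimum qualifying distance) are discarded rather than fractionally
assigned.  Hamming, not edit, distance is used: indels inside a barcode are
not rescued.

The RCP half decodes row/column/plate index tags that identify the well of
origin of each read in arrayed-plate sequencing, and calls a consensus
barcode pair plus a purity flag per well.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .design import BARCODE_LENGTH, CountMatrix, ScreenDesign

__all__ = [
    "AmpliconScheme",
    "FusedReadCall",
    "RcpScheme",
    "WellAssignment",
    "match_barcode",
    "parse_fused_reads",
    "tally_counts",
    "count_screen",
    "demultiplex_rcp",
    "call_well_barcodes",
    "hamming",
    "reverse_complement",
    "open_fastq",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming: unequal lengths")
    return sum(x != y for x, y in zip(a, b))


def open_fastq(path):
    """Open a possibly gzipped FASTQ for text reading."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(source) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a path, handle, or iterable of sequences."""
    if hasattr(source, "read") or isinstance(source, (str, bytes)):
        handle = open_fastq(source) if isinstance(source, (str, bytes)) else source
        for title, seq, _qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq.upper()
    else:  # pre-parsed iterable of sequences or (id, seq) tuples
        for i, item in enumerate(source):
            if isinstance(item, tuple):
                yield item[0], item[1].upper()
            else:
                yield f"read{i}", item.upper()


# ---------------------------------------------------------------------------
# Barcode matching
# ---------------------------------------------------------------------------

def match_barcode(
    observed: str, dictionary: dict[str, str], max_mismatch: int
) -> tuple[str | None, str]:
    """Resolve a 25-mer against a barcode dictionary (sequence -> id).

    Returns ``(id, "matched")`` for a unique best hit within ``max_mismatch``,
    ``(None, "none")`` if nothing qualifies, ``(None, "ambiguous")`` when two
    or more entries tie at the minimum qualifying distance.
    """
    if len(observed) != BARCODE_LENGTH:
        raise ValueError(
            f"match_barcode expects a {BARCODE_LENGTH}-mer "
            f"(anchor extraction must have succeeded); got length {len(observed)}"
        )
    if not dictionary:
        raise ValueError("match_barcode: empty dictionary")
    hit = dictionary.get(observed)
    if hit is not None:  # exact match cannot be tied: sequences are unique
        return hit, "matched"
    if max_mismatch == 0:
        return None, "none"
    best_d = max_mismatch + 1
    best_id: str | None = None
    tied = False
    for seq, ident in dictionary.items():
        d = 0
        for x, y in zip(observed, seq):
            if x != y:
                d += 1
                if d > max_mismatch:
                    break
        if d > max_mismatch:
            continue
        if d < best_d:
            best_d, best_id, tied = d, ident, False
        elif d == best_d:
            tied = True
    if best_id is None:
        return None, "none"
    if tied:
        return None, "ambiguous"
    return best_id, "matched"


# ---------------------------------------------------------------------------
# Fused-read parsing
# ---------------------------------------------------------------------------

@dataclass
class AmpliconScheme:
    """Layout of the fused-barcode amplicon.

    Single-end layout (plasmid forward strand):
    ``upstream_anchor + bait_barcode + spacer_anchor + prey_barcode +
    downstream_anchor``.  In paired-end mode, mate 1 reads the upstream
    anchor and bait barcode; mate 2 reads (reverse-complemented) the
    downstream anchor and prey barcode.
    """

    upstream_anchor: str
    spacer_anchor: str
    downstream_anchor: str
    fusion_type: str = "BC1BC1"
    max_mismatch_anchor: int = 3
    max_mismatch_barcode: int = 2
    paired: bool = False

    def __post_init__(self) -> None:
        for name in ("upstream_anchor", "spacer_anchor", "downstream_anchor"):
            seq = getattr(self, name)
            if not seq:
                raise ValueError(f"AmpliconScheme: {name} must be non-empty")
            setattr(self, name, seq.upper())
        if self.max_mismatch_anchor < 0 or self.max_mismatch_barcode < 0:
            raise ValueError("mismatch limits must be >= 0")
        if self.fusion_type not in ("BC1BC1", "BC2BC2"):
            raise ValueError(f"unknown fusion type {self.fusion_type!r}")

    @property
    def barcode_tier(self) -> str:
        return "BC1" if self.fusion_type == "BC1BC1" else "BC2"

    def read_length(self) -> int:
        return (
            len(self.upstream_anchor)
            + len(self.spacer_anchor)
            + len(self.downstream_anchor)
            + 2 * BARCODE_LENGTH
        )

    def build_read(self, bait_bc: str, prey_bc: str) -> str:
        return (
            self.upstream_anchor
            + bait_bc
            + self.spacer_anchor
            + prey_bc
            + self.downstream_anchor
        )

    def to_dict(self) -> dict:
        return {
            "upstream_anchor": self.upstream_anchor,
            "spacer_anchor": self.spacer_anchor,
            "downstream_anchor": self.downstream_anchor,
            "fusion_type": self.fusion_type,
            "max_mismatch_anchor": self.max_mismatch_anchor,
            "max_mismatch_barcode": self.max_mismatch_barcode,
            "paired": self.paired,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AmpliconScheme":
        return cls(**d)


@dataclass(frozen=True)
class FusedReadCall:
    """Outcome of demultiplexing one fused-barcode read (pair)."""

    bait_strain: str | None
    prey_strain: str | None
    status: str  # matched | unmatched-anchor | unmatched-barcode | ambiguous


def _anchor_ok(read: str, anchor: str, offset: int, max_mm: int) -> bool:
    segment = read[offset : offset + len(anchor)]
    if len(segment) < len(anchor):
        return False
    d = 0
    for x, y in zip(segment, anchor):
        if x != y:
            d += 1
            if d > max_mm:
                return False
    return True


def _extract_single(scheme: AmpliconScheme, read: str) -> tuple[str, str] | None:
    """Locate anchors at fixed offsets; return (bait 25-mer, prey 25-mer)."""
    u, s, d = scheme.upstream_anchor, scheme.spacer_anchor, scheme.downstream_anchor
    off_bait = len(u)
    off_spacer = off_bait + BARCODE_LENGTH
    off_prey = off_spacer + len(s)
    off_down = off_prey + BARCODE_LENGTH
    if len(read) < off_down + len(d):
        return None
    mm = scheme.max_mismatch_anchor
    if not (
        _anchor_ok(read, u, 0, mm)
        and _anchor_ok(read, s, off_spacer, mm)
        and _anchor_ok(read, d, off_down, mm)
    ):
        return None
    return read[off_bait:off_spacer], read[off_prey : off_prey + BARCODE_LENGTH]


def _extract_paired(scheme: AmpliconScheme, r1: str, r2: str) -> tuple[str, str] | None:
    """Mate 1: upstream anchor + bait barcode (+ spacer start).
    Mate 2: reverse complement of (spacer end + prey barcode + downstream)."""
    mm = scheme.max_mismatch_anchor
    u = scheme.upstream_anchor
    if len(r1) < len(u) + BARCODE_LENGTH or not _anchor_ok(r1, u, 0, mm):
        return None
    bait = r1[len(u) : len(u) + BARCODE_LENGTH]
    d_rc = reverse_complement(scheme.downstream_anchor)
    if len(r2) < len(d_rc) + BARCODE_LENGTH or not _anchor_ok(r2, d_rc, 0, mm):
        return None
    prey = reverse_complement(r2[len(d_rc) : len(d_rc) + BARCODE_LENGTH])
    return bait, prey


def parse_fused_reads(
    reads,
    scheme: AmpliconScheme,
    design: ScreenDesign,
    reads2=None,
) -> Iterator[FusedReadCall]:
    """Demultiplex a fused-barcode read stream into per-read calls.

    ``reads`` (and ``reads2`` in paired mode) may be FASTQ paths/handles or
    iterables of sequences.  Reads whose anchors cannot be located at the
    scheme's fixed offsets are reported as ``unmatched-anchor``; reads whose
    25-mers do not resolve uniquely in the design dictionaries are
    ``unmatched-barcode`` or ``ambiguous``.
    """
    tier = scheme.barcode_tier
    bait_dict = design.barcode_dict("bait", tier)
    prey_dict = design.barcode_dict("prey", tier)
    mm = scheme.max_mismatch_barcode

    if scheme.paired:
        if reads2 is None:
            raise ValueError("paired scheme requires a second read stream")
        stream = (
            (s1, s2)
            for (_, s1), (_, s2) in zip(iter_fastq(reads), iter_fastq(reads2))
        )
    else:
        stream = ((s, None) for _, s in iter_fastq(reads))

    for r1, r2 in stream:
        if scheme.paired:
            extracted = _extract_paired(scheme, r1, r2)
        else:
            extracted = _extract_single(scheme, r1)
        if extracted is None:
            yield FusedReadCall(None, None, "unmatched-anchor")
            continue
        bait_obs, prey_obs = extracted
        bait_id, st_b = match_barcode(bait_obs, bait_dict, mm)
        prey_id, st_p = match_barcode(prey_obs, prey_dict, mm)
        if bait_id is not None and prey_id is not None:
            yield FusedReadCall(bait_id, prey_id, "matched")
        elif "ambiguous" in (st_b, st_p):
            yield FusedReadCall(None, None, "ambiguous")
        else:
            yield FusedReadCall(None, None, "unmatched-barcode")


def tally_counts(
    calls: Iterable[FusedReadCall],
    design: ScreenDesign,
    condition: str,
    fusion_type: str,
    replicate: str,
) -> CountMatrix:
    """Accumulate per-read calls into a bait × prey count matrix.

    Read conservation holds exactly: ``counts.sum() + unmatched`` equals the
    number of calls consumed.
    """
    import numpy as np

    bait_idx = {b: i for i, b in enumerate(design.bait_ids)}
    prey_idx = {p: j for j, p in enumerate(design.prey_ids)}
    counts = np.zeros((len(bait_idx), len(prey_idx)), dtype=np.int64)
    unmatched = 0
    for call in calls:
        if call.status == "matched":
            i = bait_idx.get(call.bait_strain)
            j = prey_idx.get(call.prey_strain)
            if i is None or j is None:  # barcode known but strain not in design
                unmatched += 1
                continue
            counts[i, j] += 1
        else:
            unmatched += 1
    return CountMatrix(
        axis_baits=design.bait_ids,
        axis_preys=design.prey_ids,
        counts=counts,
        condition=condition,
        fusion_type=fusion_type,
        replicate=replicate,
        unmatched=unmatched,
    )


def count_screen(
    reads,
    scheme: AmpliconScheme,
    design: ScreenDesign,
    condition: str,
    replicate: str,
    reads2=None,
) -> CountMatrix:
    """parse_fused_reads + tally_counts in one call."""
    calls = parse_fused_reads(reads, scheme, design, reads2=reads2)
    return tally_counts(calls, design, condition, scheme.fusion_type, replicate)


# ---------------------------------------------------------------------------
# RCP-PCR well decoding
# ---------------------------------------------------------------------------

@dataclass
class RcpScheme:
    """Row/column/plate index-tag layout for arrayed-plate sequencing.

    Read layout: ``plate_tag + row_tag + col_tag + bc1 + linker + bc2``.
    Tags must be unique within each tier; tolerant matching assigns a read
    to the unique tag within ``max_mismatch`` (dropped otherwise).
    """

    plate_tags: dict[str, str]  # label -> sequence
    row_tags: dict[str, str]
    col_tags: dict[str, str]
    linker: str = "GGATCC"
    purity_threshold: float = 0.8
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        for name in ("plate_tags", "row_tags", "col_tags"):
            tags = getattr(self, name)
            seqs = list(tags.values())
            if len(set(seqs)) != len(seqs):
                raise ValueError(f"RcpScheme: duplicate sequences in {name}")
            if len(set(map(len, seqs))) > 1:
                raise ValueError(f"RcpScheme: {name} must share one length")
        if not 0.0 <= self.purity_threshold <= 1.0:
            raise ValueError("purity_threshold must lie in [0, 1]")

    def wells(self) -> list[tuple[str, str, str]]:
        return [
            (p, r, c)
            for p in self.plate_tags
            for r in self.row_tags
            for c in self.col_tags
        ]


@dataclass
class WellAssignment:
    """Consensus barcode call for one well."""

    plate: str
    row: str
    col: str
    consensus_bc1: str
    consensus_bc2: str
    purity: float
    n_reads: int
    flag: str  # clean | mixed | empty


def _match_tag(observed: str, tags: dict[str, str], max_mm: int) -> str | None:
    best_d = max_mm + 1
    best: str | None = None
    tied = False
    for label, seq in tags.items():
        d = hamming(observed, seq)
        if d < best_d:
            best_d, best, tied = d, label, False
        elif d == best_d:
            tied = True
    return None if best is None or tied else best


def demultiplex_rcp(
    reads, scheme: RcpScheme
) -> tuple[dict[tuple[str, str, str], Counter], Counter]:
    """Assign reads to wells by their plate/row/column tags.

    Returns (well -> Counter of (bc1, bc2) string pairs, drop-reason tally).
    Every read lands in exactly one well or one drop bucket.
    """
    p_len = len(next(iter(scheme.plate_tags.values())))
    r_len = len(next(iter(scheme.row_tags.values())))
    c_len = len(next(iter(scheme.col_tags.values())))
    bc1_off = p_len + r_len + c_len
    link_off = bc1_off + BARCODE_LENGTH
    bc2_off = link_off + len(scheme.linker)
    min_len = bc2_off + BARCODE_LENGTH

    tallies: dict[tuple[str, str, str], Counter] = {}
    drops: Counter = Counter()
    for _, seq in iter_fastq(reads):
        if len(seq) < min_len:
            drops["too-short"] += 1
            continue
        plate = _match_tag(seq[:p_len], scheme.plate_tags, scheme.max_mismatch)
        row = _match_tag(seq[p_len : p_len + r_len], scheme.row_tags, scheme.max_mismatch)
        col = _match_tag(seq[p_len + r_len : bc1_off], scheme.col_tags, scheme.max_mismatch)
        if plate is None or row is None or col is None:
            drops["unmatched-tag"] += 1
            continue
        bc1 = seq[bc1_off:link_off]
        bc2 = seq[bc2_off : bc2_off + BARCODE_LENGTH]
        tallies.setdefault((plate, row, col), Counter())[(bc1, bc2)] += 1
    return tallies, drops


def call_well_barcodes(
    tallies: dict[tuple[str, str, str], Counter], scheme: RcpScheme
) -> list[WellAssignment]:
    """Call a consensus (bc1, bc2) and purity for every well of the scheme.

    Wells with no reads are flagged ``empty``; wells whose consensus carries
    less than ``purity_threshold`` of the reads are flagged ``mixed``.
    """
    out = []
    for well in scheme.wells():
        plate, row, col = well
        counter = tallies.get(well)
        if not counter:
            out.append(WellAssignment(plate, row, col, "", "", 0.0, 0, "empty"))
            continue
        n = sum(counter.values())
        (bc1, bc2), top = counter.most_common(1)[0]
        purity = top / n
        flag = "clean" if purity >= scheme.purity_threshold else "mixed"
        out.append(WellAssignment(plate, row, col, bc1, bc2, purity, n, flag))
    return out


def generate_tag_set(
    n: int, length: int = 10, min_distance: int = 5, seed: int = 0
) -> list[str]:
    """Greedy seeded generation of index tags with pairwise Hamming >= min_distance."""
    import numpy as np

    rng = np.random.default_rng(seed)
    bases = "ACGT"
    tags: list[str] = []
    attempts = 0
    while len(tags) < n:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not construct tag set; relax constraints")
        cand = "".join(bases[i] for i in rng.integers(0, 4, size=length))
        if all(hamming(cand, t) >= min_distance for t in tags):
            tags.append(cand)
    return tags
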