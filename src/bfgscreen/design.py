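"""Core data model and I/O for barcode-fusion two-hybrid screen designs.

A screen interrogates a bait library against a prey library.  Every strain
carries two strain-specific 25-bp barcodes (BC1 and BC2) at a lox-flanked
locus; Cre-mediated recombination in diploids swaps barcodes between the bait
and prey plasmids so that a single sequencing read of a chimeric BC1-BC1 or
BC2-BC2 fusion identifies one bait-prey combination.  This module holds the
shared containers — barcodes, strains, designs, count matrices, reference
pair sets — and their TSV round-trip I/O.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Barcode",
    "Strain",
    "ScreenDesign",
    "CountMatrix",
    "ReferenceSet",
    "canonical_pair",
    "load_design",
    "write_design",
    "read_counts",
    "write_counts",
    "load_reference",
    "write_reference",
]

BARCODE_LENGTH = 25
_VALID_LOCI = frozenset({"bait-BC1", "bait-BC2", "prey-BC1", "prey-BC2"})
_DNA_RE = re.compile(r"^[ACGT]+$")


class DesignFormatError(ValueError):
    """A design, counts or reference table violates its format contract."""


@dataclass(frozen=True)
class Barcode:
    """One 25-bp strain-identifying barcode at a specific locus."""

    id: str
    sequence: str
    locus: str

    def __post_init__(self) -> None:
        if self.locus not in _VALID_LOCI:
            raise DesignFormatError(f"unknown barcode locus {self.locus!r}")
        if len(self.sequence) != BARCODE_LENGTH:
            raise DesignFormatError(
                f"barcode {self.id!r}: length {len(self.sequence)} != {BARCODE_LENGTH}"
            )
        if not _DNA_RE.match(self.sequence):
            raise DesignFormatError(f"barcode {self.id!r}: non-ACGT characters")


@dataclass(frozen=True)
class Strain:
    """A single barcoded bait or prey strain.

    Strain identity is the (ORF, barcode-pair) combination, not the ORF:
    one ORF may be represented by several independently barcoded strains
    (barcode replicates), which are scored separately before averaging.
    """

    strain_id: str
    role: str  # "bait" | "prey"
    orf_id: str
    bc1: Barcode
    bc2: Barcode

    def __post_init__(self) -> None:
        if self.role not in ("bait", "prey"):
            raise DesignFormatError(f"strain {self.strain_id!r}: bad role {self.role!r}")
        if self.bc1.locus != f"{self.role}-BC1" or self.bc2.locus != f"{self.role}-BC2":
            raise DesignFormatError(
                f"strain {self.strain_id!r}: barcode loci inconsistent with role"
            )


def canonical_pair(orf_a: str, orf_b: str) -> tuple[str, str]:
    """Orientation-free key for an unordered ORF pair.

    Screens test X→Y and Y→X separately but reference interaction sets are
    unordered; both orientations map to the same lexicographically sorted
    key.  Homodimers (X, X) map to (X, X).
    """
    if not orf_a or not orf_b:
        raise ValueError("canonical_pair: ORF ids must be non-empty")
    return (orf_a, orf_b) if orf_a <= orf_b else (orf_b, orf_a)


@dataclass
class ScreenDesign:
    """The bait × prey library layout of one screen."""

    baits: list[Strain]
    preys: list[Strain]
    conditions: list[str] = field(default_factory=lambda: ["+His", "-His", "3-AT"])
    replicates: list[str] = field(default_factory=lambda: ["r1"])
    fusion_types: tuple[str, ...] = ("BC1BC1", "BC2BC2")
    calibration_pairs: list[tuple[str, str]] = field(default_factory=list)
    autoactivator_orfs: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.baits or not self.preys:
            raise DesignFormatError("design needs at least one bait and one prey")
        if len(set(self.conditions)) != len(self.conditions):
            raise DesignFormatError("condition labels must be unique")
        for strains, role in ((self.baits, "bait"), (self.preys, "prey")):
            seqs: dict[tuple[str, str], str] = {}
            pairs: set[tuple[str, str]] = set()
            ids: set[str] = set()
            for s in strains:
                if s.role != role:
                    raise DesignFormatError(f"strain {s.strain_id!r} in wrong library")
                if s.strain_id in ids:
                    raise DesignFormatError(f"duplicate strain id {s.strain_id!r}")
                ids.add(s.strain_id)
                for bc in (s.bc1, s.bc2):
                    key = (bc.locus, bc.sequence)
                    if key in seqs:
                        raise DesignFormatError(
                            f"duplicate barcode sequence at locus {bc.locus} "
                            f"(strains {seqs[key]!r} and {s.strain_id!r})"
                        )
                    seqs[key] = s.strain_id
                pair = (s.bc1.sequence, s.bc2.sequence)
                if pair in pairs:
                    raise DesignFormatError(
                        f"duplicate barcode pair for strain {s.strain_id!r}"
                    )
                pairs.add(pair)
        self._index()

    def _index(self) -> None:
        self._by_id = {s.strain_id: s for s in self.baits + self.preys}
        # locus -> barcode sequence -> strain_id
        self._seq_lookup: dict[str, dict[str, str]] = {loc: {} for loc in _VALID_LOCI}
        for s in self.baits + self.preys:
            for bc in (s.bc1, s.bc2):
                self._seq_lookup[bc.locus][bc.sequence] = s.strain_id

    # -- lookups ----------------------------------------------------------
    def strain(self, strain_id: str) -> Strain:
        return self._by_id[strain_id]

    def barcode_dict(self, role: str, bc: str) -> dict[str, str]:
        """Map barcode sequence -> strain id for one locus, e.g. ('bait','BC1')."""
        return self._seq_lookup[f"{role}-{bc}"]

    @property
    def bait_ids(self) -> list[str]:
        return [s.strain_id for s in self.baits]

    @property
    def prey_ids(self) -> list[str]:
        return [s.strain_id for s in self.preys]

    def orf_of(self, strain_id: str) -> str:
        return self._by_id[strain_id].orf_id

    def tested_orf_pairs(self) -> set[tuple[str, str]]:
        """Canonical ORF pairs covered by the bait × prey matrix."""
        bait_orfs = {s.orf_id for s in self.baits}
        prey_orfs = {s.orf_id for s in self.preys}
        return {canonical_pair(b, p) for b in bait_orfs for p in prey_orfs}


@dataclass
class CountMatrix:
    """Raw fused-barcode read counts for one condition × fusion type × replicate."""

    axis_baits: list[str]
    axis_preys: list[str]
    counts: np.ndarray
    condition: str
    fusion_type: str
    replicate: str
    unmatched: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.axis_baits), len(self.axis_preys)):
            raise DesignFormatError("count matrix shape does not match axes")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise DesignFormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any() or self.unmatched < 0:
            raise DesignFormatError("counts and unmatched tally must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.axis_baits, columns=self.axis_preys)


@dataclass
class ReferenceSet:
    """Unordered positive ORF pairs used for threshold calibration."""

    pairs: set[tuple[str, str]]
    name: str = "reference"

    def __post_init__(self) -> None:
        self.pairs = {canonical_pair(a, b) for a, b in self.pairs}

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.pairs

    def restricted_to(self, tested: set[tuple[str, str]]) -> set[tuple[str, str]]:
        return self.pairs & tested


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_DESIGN_COLS = ["strain_id", "role", "orf_id", "bc1_id", "bc1_seq", "bc2_id", "bc2_seq"]


def write_design(design: ScreenDesign, path) -> None:
    rows = [
        {
            "strain_id": s.strain_id,
            "role": s.role,
            "orf_id": s.orf_id,
            "bc1_id": s.bc1.id,
            "bc1_seq": s.bc1.sequence,
            "bc2_id": s.bc2.id,
            "bc2_seq": s.bc2.sequence,
        }
        for s in design.baits + design.preys
    ]
    pd.DataFrame(rows, columns=_DESIGN_COLS).to_csv(path, sep="\t", index=False)


def load_design(path, **kwargs) -> ScreenDesign:
    """Read a strain table TSV into a fully cross-indexed :class:`ScreenDesign`.

    Extra keyword arguments (conditions, replicates, calibration_pairs, ...)
    are passed through to the :class:`ScreenDesign` constructor.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_DESIGN_COLS) - set(df.columns)
    if missing:
        raise DesignFormatError(f"design table missing columns: {sorted(missing)}")
    baits, preys = [], []
    for row in df.itertuples(index=False):
        strain = Strain(
            strain_id=row.strain_id,
            role=row.role,
            orf_id=row.orf_id,
            bc1=Barcode(row.bc1_id, row.bc1_seq, f"{row.role}-BC1"),
            bc2=Barcode(row.bc2_id, row.bc2_seq, f"{row.role}-BC2"),
        )
        (baits if row.role == "bait" else preys).append(strain)
    return ScreenDesign(baits=baits, preys=preys, **kwargs)


def write_counts(matrix: CountMatrix, path) -> None:
    """Write one count matrix with a 3-line metadata header plus unmatched tally."""
    with open(path, "w") as fh:
        fh.write(f"#condition={matrix.condition}\n")
        fh.write(f"#fusion_type={matrix.fusion_type}\n")
        fh.write(f"#replicate={matrix.replicate}\n")
        fh.write(f"#unmatched={matrix.unmatched}\n")
        matrix.to_frame().to_csv(fh, sep="\t", index_label="bait_strain")


def read_counts(path) -> CountMatrix:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].rstrip("\n").partition("=")
            meta[key] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    for key in ("condition", "fusion_type", "replicate"):
        if key not in meta:
            raise DesignFormatError(f"counts file missing #{key}= header")
    return CountMatrix(
        axis_baits=[str(i) for i in df.index],
        axis_preys=[str(c) for c in df.columns],
        counts=df.to_numpy(),
        condition=meta["condition"],
        fusion_type=meta["fusion_type"],
        replicate=meta["replicate"],
        unmatched=int(meta.get("unmatched", 0)),
    )


def write_reference(ref: ReferenceSet, path) -> None:
    rows = [{"orf_a": a, "orf_b": b, "source": ref.name} for a, b in sorted(ref.pairs)]
    pd.DataFrame(rows, columns=["orf_a", "orf_b", "source"]).to_csv(
        path, sep="\t", index=False
    )


def load_reference(path, name: str | None = None) -> ReferenceSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"orf_a", "orf_b"} <= set(df.columns):
        raise DesignFormatError("reference table needs orf_a and orf_b columns")
    pairs = {canonical_pair(a, b) for a, b in zip(df["orf_a"], df["orf_b"])}
    if name is None:
        name = str(df["source"].iloc[0]) if "source" in df.columns and len(df) else "reference"
    return ReferenceSet(pairs=pairs, name=name)
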