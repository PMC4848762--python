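"""Forward Monte-Carlo simulation of a pooled barcode-fusion two-hybrid screen.

The simulator reproduces the population genetics of the screen, stage by
stage: log-normally skewed haploid strain abundances; *en masse* mating into
a bait × prey diploid pool; growth selection in which true interactors (and
auto-activating baits) out-compete the leaky background; Cre-mediated
barcode fusion of a fraction of cells (only fused loci are amplifiable);
serial molecule bottlenecks at plasmid extraction and PCR templating; and
finally multinomial read sampling, independently per fused-barcode variant
and replicate.  Every stage's per-pair molecule counts are recorded in a
ground-truth ledger, which downstream modules use as an exact oracle.

Growth under selection is modeled as a single multinomial reweighting of the
diploid pool rather than explicit generations: only relative abundances
reach the sequencer.  The survival weight of a diploid is
``(leakage + interaction_strength·1[true pair]) × autoactivator_multiplier``
so that an auto-activating bait scales its whole row — background and true
signal alike — which is exactly the pattern the per-bait background
correction in :mod:`bfgscreen.scoring` removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import Barcode, CountMatrix, ScreenDesign, Strain, canonical_pair
from .fusion import DEFAULT_FLANKS, LOX2272, LOXP
from .readcount import AmpliconScheme, RcpScheme, generate_tag_set

__all__ = [
    "SimulationParams",
    "SimLedger",
    "CoverageReport",
    "simulate_design",
    "simulate_screen",
    "emit_reads",
    "write_fastq",
    "bottleneck_coverage",
    "simulate_junction_reads",
    "simulate_rcp_plate",
    "default_scheme",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# priming-site anchors of the fused-barcode amplicon; the spacer between the
# two 25-mers is the lox site the fusion was created at
_UP_ANCHOR = {"BC1BC1": "ACTGGCCGTCGTTTTACA", "BC2BC2": "GTAAAACGACGGCCAGTG"}
_DOWN_ANCHOR = {"BC1BC1": "CAGGAAACAGCTATGACC", "BC2BC2": "GGAAACAGCTATGACCAT"}
_SPACER = {"BC1BC1": LOXP, "BC2BC2": LOX2272}


def default_scheme(fusion_type: str = "BC1BC1", **kwargs) -> AmpliconScheme:
    """The amplicon layout the simulator emits reads with."""
    return AmpliconScheme(
        upstream_anchor=_UP_ANCHOR[fusion_type],
        spacer_anchor=_SPACER[fusion_type],
        downstream_anchor=_DOWN_ANCHOR[fusion_type],
        fusion_type=fusion_type,
        **kwargs,
    )


@dataclass
class SimulationParams:
    """Study conditions of one simulated screen.

    Magnitudes mirror a real screen of ~100×100 ORFs with two barcode
    replicates per ORF: ~1e8 plated cells, a plasmid-extraction bottleneck
    of ~100 molecules per distinct pair, ~20% of cells yielding fused
    barcodes, and ~2e6 reads per matrix.
    """

    n_bait_orfs: int = 100
    n_prey_orfs: int = 100
    barcodes_per_orf: int = 2
    abundance_sigma: float = 1.0
    true_interaction_density: float = 0.05
    interaction_strength: float = 1.0
    autoactivator_fraction: float = 0.05
    autoactivator_strength: float = 20.0
    leakage: float = 1e-3
    stringency_3at: float = 0.1  # multiplies leakage under 3-AT
    mating_cells: int = 10_000_000
    plated_cells: int = 100_000_000
    extraction_molecules: int = 4_000_000
    pcr_template_molecules: int = 2_000_000
    fusion_probability: float = 0.2
    read_depth: int = 2_000_000
    conditions: tuple[str, ...] = ("+His", "-His", "3-AT")
    n_replicates: int = 4
    barcode_error_rate: float = 0.0
    seed: int = 0
    # sampling noise can be re-drawn while holding design+truth fixed
    sampling_seed: int | None = None
    # per-bait-ORF background multipliers applied on top of random assignment
    autoactivator_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "n_bait_orfs", "n_prey_orfs", "barcodes_per_orf", "mating_cells",
            "plated_cells", "extraction_molecules", "pcr_template_molecules",
            "read_depth", "n_replicates",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimulationParams.{name} must be > 0")
        for name in (
            "true_interaction_density", "autoactivator_fraction",
            "fusion_probability", "barcode_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"SimulationParams.{name} must lie in [0, 1]")
        if self.abundance_sigma < 0:
            raise ValueError("abundance_sigma must be >= 0")


@dataclass
class SimLedger:
    """Ground truth of one simulated screen."""

    params: SimulationParams
    design: ScreenDesign
    true_interactions: set[tuple[str, str]]  # canonical ORF pairs
    autoactivators: dict[str, float]  # bait ORF -> background multiplier
    bait_abundance: np.ndarray
    prey_abundance: np.ndarray
    mating_counts: np.ndarray
    stage_counts: dict[tuple[str, str], dict[str, np.ndarray]]  # (cond, rep) -> stage
    count_matrices: dict[tuple[str, str, str], CountMatrix]  # (cond, ftype, rep)

    def true_pair_mask(self) -> np.ndarray:
        bait_orfs = [s.orf_id for s in self.design.baits]
        prey_orfs = [s.orf_id for s in self.design.preys]
        mask = np.zeros((len(bait_orfs), len(prey_orfs)), dtype=bool)
        for i, b in enumerate(bait_orfs):
            for j, p in enumerate(prey_orfs):
                mask[i, j] = canonical_pair(b, p) in self.true_interactions
        return mask


def _random_barcodes(rng: np.random.Generator, n: int, used: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=25))
        if seq not in used:
            used.add(seq)
            out.append(seq)
    return out


def simulate_design(params: SimulationParams, rng: np.random.Generator) -> ScreenDesign:
    """Draw a random barcoded bait and prey library."""
    used: set[str] = set()

    def make(role: str, n_orfs: int) -> list[Strain]:
        strains = []
        for o in range(n_orfs):
            orf = f"{role.upper()}{o:04d}"
            bc1s = _random_barcodes(rng, params.barcodes_per_orf, used)
            bc2s = _random_barcodes(rng, params.barcodes_per_orf, used)
            for k in range(params.barcodes_per_orf):
                sid = f"{role[0]}{o:04d}.{k}"
                strains.append(
                    Strain(
                        strain_id=sid,
                        role=role,
                        orf_id=orf,
                        bc1=Barcode(f"{sid}-1", bc1s[k], f"{role}-BC1"),
                        bc2=Barcode(f"{sid}-2", bc2s[k], f"{role}-BC2"),
                    )
                )
        return strains

    return ScreenDesign(
        baits=make("bait", params.n_bait_orfs),
        preys=make("prey", params.n_prey_orfs),
        conditions=list(params.conditions),
        replicates=[f"r{i + 1}" for i in range(params.n_replicates)],
    )


def _subsample(rng: np.random.Generator, x: np.ndarray, n: int) -> np.ndarray:
    """Multinomial subsample of molecule counts to total n (capped at available)."""
    total = int(x.sum())
    if total == 0 or n >= total:
        return x.copy()
    p = x.ravel() / total
    return rng.multinomial(n, p).reshape(x.shape)


def simulate_screen(
    params: SimulationParams,
) -> tuple[dict[tuple[str, str, str], CountMatrix], SimLedger]:
    """Run the full forward simulation; bit-identical for identical seeds."""
    rng_design = np.random.default_rng(params.seed)
    sampling_seed = (
        params.sampling_seed if params.sampling_seed is not None else params.seed + 1
    )
    rng = np.random.default_rng(sampling_seed)

    design = simulate_design(params, rng_design)
    bait_orfs = np.array([s.orf_id for s in design.baits])
    prey_orfs = np.array([s.orf_id for s in design.preys])
    nb, np_ = len(bait_orfs), len(prey_orfs)

    # ground truth interactions over the ORF grid
    n_pairs_orf = params.n_bait_orfs * params.n_prey_orfs
    n_true = int(round(params.true_interaction_density * n_pairs_orf))
    chosen = rng_design.choice(n_pairs_orf, size=n_true, replace=False)
    u_bait = [f"BAIT{o:04d}" for o in range(params.n_bait_orfs)]
    u_prey = [f"PREY{o:04d}" for o in range(params.n_prey_orfs)]
    true_pairs = {
        canonical_pair(u_bait[i // params.n_prey_orfs], u_prey[i % params.n_prey_orfs])
        for i in chosen
    }

    # auto-activating baits
    n_auto = int(round(params.autoactivator_fraction * params.n_bait_orfs))
    auto_orfs = rng_design.choice(params.n_bait_orfs, size=n_auto, replace=False)
    autoactivators = {u_bait[i]: params.autoactivator_strength for i in auto_orfs}
    autoactivators.update(params.autoactivator_overrides)
    design.autoactivator_orfs = set(autoactivators)

    # haploid strain abundances (log-normal), mating ∝ outer product
    bait_ab = rng.lognormal(0.0, params.abundance_sigma, size=nb)
    prey_ab = rng.lognormal(0.0, params.abundance_sigma, size=np_)
    p_mating = np.outer(bait_ab, prey_ab)
    p_mating /= p_mating.sum()
    mating = rng.multinomial(params.mating_cells, p_mating.ravel()).reshape(nb, np_)

    true_mask = np.zeros((nb, np_), dtype=bool)
    true_set = true_pairs
    for i in range(nb):
        for j in range(np_):
            true_mask[i, j] = canonical_pair(bait_orfs[i], prey_orfs[j]) in true_set
    auto_mult = np.array([autoactivators.get(o, 1.0) for o in bait_orfs])

    counts_out: dict[tuple[str, str, str], CountMatrix] = {}
    stage_counts: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    replicates = [f"r{i + 1}" for i in range(params.n_replicates)]

    for cond in params.conditions:
        if cond == "+His":
            weight = np.ones((nb, np_))
        else:
            leak = params.leakage
            if cond == "3-AT":
                leak = leak * params.stringency_3at
            weight = (leak + params.interaction_strength * true_mask) * auto_mult[:, None]
        for rep in replicates:
            w = mating * weight
            wsum = w.sum()
            if wsum == 0:
                plated = np.zeros_like(mating)
            else:
                plated = rng.multinomial(
                    params.plated_cells, (w / wsum).ravel()
                ).reshape(nb, np_)
            fused = rng.binomial(plated, params.fusion_probability)
            extraction = _subsample(rng, fused, params.extraction_molecules)
            pcr = _subsample(rng, extraction, params.pcr_template_molecules)
            stage_counts[(cond, rep)] = {
                "mating": mating,
                "plated": plated,
                "fused": fused,
                "extraction": extraction,
                "pcr": pcr,
            }
            pcr_total = int(pcr.sum())
            for ftype in design.fusion_types:
                if pcr_total == 0:
                    reads = np.zeros_like(pcr)
                else:
                    reads = rng.multinomial(
                        params.read_depth, (pcr / pcr_total).ravel()
                    ).reshape(nb, np_)
                counts_out[(cond, ftype, rep)] = CountMatrix(
                    axis_baits=design.bait_ids,
                    axis_preys=design.prey_ids,
                    counts=reads,
                    condition=cond,
                    fusion_type=ftype,
                    replicate=rep,
                )

    ledger = SimLedger(
        params=params,
        design=design,
        true_interactions=true_pairs,
        autoactivators=autoactivators,
        bait_abundance=bait_ab,
        prey_abundance=prey_ab,
        mating_counts=mating,
        stage_counts=stage_counts,
        count_matrices=counts_out,
    )
    return counts_out, ledger


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

def emit_reads(
    counts: CountMatrix,
    scheme: AmpliconScheme,
    design: ScreenDesign,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Emit one read per sampled molecule, with per-base substitution errors.

    Read ids encode the intended (bait strain, prey strain) so the read
    stream itself is a ledger for the demultiplexer.
    """
    rng = np.random.default_rng(seed)
    tier = "bc1" if scheme.fusion_type == "BC1BC1" else "bc2"
    reads: list[tuple[str, str]] = []
    nonzero = np.argwhere(counts.counts > 0)
    for i, j in nonzero:
        bait = design.strain(counts.axis_baits[i])
        prey = design.strain(counts.axis_preys[j])
        base = scheme.build_read(
            getattr(bait, tier).sequence, getattr(prey, tier).sequence
        )
        n = int(counts.counts[i, j])
        if error_rate > 0:
            arr = np.frombuffer(base.encode(), dtype=np.uint8)
            tiled = np.tile(arr, (n, 1))
            hit = rng.random(tiled.shape) < error_rate
            # substitute with a uniformly chosen *different* base
            shift = rng.integers(1, 4, size=int(hit.sum()))
            idx = np.searchsorted(_BASES, tiled[hit])  # ACGT are sorted bytes
            tiled[hit] = _BASES[(idx + shift) % 4]
            seqs = [t.tobytes().decode() for t in tiled]
        else:
            seqs = [base] * n
        bid, pid = bait.strain_id, prey.strain_id
        for k, seq in enumerate(seqs):
            reads.append((f"sim:{bid}:{pid}:{k}", seq))
    return reads


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Bottleneck coverage analytics
# ---------------------------------------------------------------------------

@dataclass
class CoverageReport:
    """Per-pair molecule representation at each population bottleneck."""

    stage_order: list[str]
    stage_means: dict[str, float]  # mean molecules per distinct pair
    min_stage: str
    fraction_covered: dict[int, float]  # c -> fraction of pairs with >= c at min stage
    n_pairs: int
    n_monte_carlo: int


def bottleneck_coverage(
    params: SimulationParams, n_monte_carlo: int = 3
) -> CoverageReport:
    """Monte-Carlo expectation of per-pair molecule counts at each stage.

    Runs the non-selective (+His) chain — mating → plating → fusion →
    extraction → PCR templating → reads — and reports, per stage, the mean
    number of molecules representing each distinct strain pair, averaged
    over Monte-Carlo draws.  The most restrictive stage is the molecule
    bottleneck that limits quantification.
    """
    if n_monte_carlo < 1:
        raise ValueError("n_monte_carlo must be >= 1")
    nb = params.n_bait_orfs * params.barcodes_per_orf
    np_ = params.n_prey_orfs * params.barcodes_per_orf
    n_pairs = nb * np_
    order = ["mating", "plated", "fused", "extraction", "pcr", "reads"]
    sums = {st: 0.0 for st in order}
    min_counts = np.zeros(n_pairs)

    rng = np.random.default_rng(params.seed)
    for _ in range(n_monte_carlo):
        bait_ab = rng.lognormal(0.0, params.abundance_sigma, size=nb)
        prey_ab = rng.lognormal(0.0, params.abundance_sigma, size=np_)
        p = np.outer(bait_ab, prey_ab).ravel()
        p /= p.sum()
        mating = rng.multinomial(params.mating_cells, p)
        plated = rng.multinomial(params.plated_cells, p)  # no selection in +His
        fused = rng.binomial(plated, params.fusion_probability)
        extraction = _subsample(rng, fused, params.extraction_molecules)
        pcr = _subsample(rng, extraction, params.pcr_template_molecules)
        reads = _subsample(rng, pcr, params.read_depth)
        draws = {
            "mating": mating, "plated": plated, "fused": fused,
            "extraction": extraction, "pcr": pcr, "reads": reads,
        }
        for st in order:
            sums[st] += draws[st].sum() / n_pairs
        min_counts += draws[min(order, key=lambda s: draws[s].sum())]

    stage_means = {st: sums[st] / n_monte_carlo for st in order}
    min_stage = min(order, key=lambda s: stage_means[s])
    # fraction of pairs covered at the minimum stage (last draw basis: use
    # accumulated per-pair averages over MC draws)
    per_pair = min_counts / n_monte_carlo
    fraction_covered = {c: float((per_pair >= c).mean()) for c in (1, 10, 100)}
    return CoverageReport(
        stage_order=order,
        stage_means=stage_means,
        min_stage=min_stage,
        fraction_covered=fraction_covered,
        n_pairs=n_pairs,
        n_monte_carlo=n_monte_carlo,
    )


# ---------------------------------------------------------------------------
# Shotgun junction reads (fusion-efficiency ground truth)
# ---------------------------------------------------------------------------

def simulate_junction_reads(
    n_reads: int,
    p_fused: float,
    read_length: int = 60,
    error_rate: float = 0.0,
    seed: int = 0,
    flank_refs: dict | None = None,
) -> tuple[list[tuple[str, str]], dict]:
    """Simulate shotgun reads spanning lox junctions of a plasmid pool.

    Each read carries one lox site (loxP or lox2272, equiprobable) embedded
    in random sequence; with probability ``p_fused`` the junction is
    chimeric (bait flank on one side, prey flank on the other), otherwise
    parental.  Reads are emitted on a random strand.  Returns the reads and
    a ledger with the planted parental/chimeric tallies.
    """
    if not 0.0 <= p_fused <= 1.0:
        raise ValueError("p_fused must lie in [0, 1]")
    refs = flank_refs if flank_refs is not None else DEFAULT_FLANKS
    rng = np.random.default_rng(seed)
    motifs = {"loxP": LOXP, "lox2272": LOX2272}
    sites = list(motifs)
    core_len = 7 + len(LOXP) + 7

    reads: list[tuple[str, str]] = []
    ledger = {"n_parental": 0, "n_chimeric": 0, "per_site": {s: [0, 0] for s in sites}}
    comp = str.maketrans("ACGT", "TGCA")
    for r in range(n_reads):
        site = sites[int(rng.integers(0, 2))]
        fused = rng.random() < p_fused
        if fused:
            up_origin, down_origin = ("bait", "prey") if rng.random() < 0.5 else ("prey", "bait")
            ledger["n_chimeric"] += 1
            ledger["per_site"][site][1] += 1
        else:
            o = "bait" if rng.random() < 0.5 else "prey"
            up_origin = down_origin = o
            ledger["n_parental"] += 1
            ledger["per_site"][site][0] += 1
        core = (
            refs[site]["upstream"][up_origin]
            + motifs[site]
            + refs[site]["downstream"][down_origin]
        )
        pad = read_length - core_len
        offset = int(rng.integers(0, pad + 1)) if pad > 0 else 0
        left = "".join("ACGT"[i] for i in rng.integers(0, 4, size=offset))
        right = "".join("ACGT"[i] for i in rng.integers(0, 4, size=max(pad - offset, 0)))
        seq = left + core + right
        if error_rate > 0:
            chars = list(seq)
            for k in range(len(chars)):
                if rng.random() < error_rate:
                    chars[k] = "ACGT"[int(rng.integers(0, 4))]
            seq = "".join(chars)
        if rng.random() < 0.5:
            seq = seq.translate(comp)[::-1]
        reads.append((f"junc{r}", seq))
    return reads, ledger


# ---------------------------------------------------------------------------
# RCP plate generator
# ---------------------------------------------------------------------------

def simulate_rcp_plate(
    n_reads_per_well: int = 100,
    tag_error_rate: float = 0.01,
    n_contaminated_wells: int = 0,
    contamination_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], RcpScheme, dict, list]:
    """Synthesize one 384-well RCP-PCR plate read set with known truth.

    Index tags are generated with pairwise Hamming distance >= 5, so single
    tag errors are corrected and double errors are dropped rather than
    misassigned.  Contaminated wells receive exactly
    ``round(contamination_fraction * n_reads_per_well)`` reads from a donor
    well's clone.  Returns (reads, scheme, well -> true (bc1, bc2),
    contaminated well list).
    """
    rng = np.random.default_rng(seed)
    tags = generate_tag_set(1 + 16 + 24, length=10, min_distance=5, seed=seed + 7)
    scheme = RcpScheme(
        plate_tags={"P1": tags[0]},
        row_tags={f"R{i + 1:02d}": t for i, t in enumerate(tags[1:17])},
        col_tags={f"C{i + 1:02d}": t for i, t in enumerate(tags[17:41])},
        purity_threshold=0.99,
        max_mismatch=1,
    )
    wells = scheme.wells()
    used: set[str] = set()
    truth = {
        w: (
            _random_barcodes(rng, 1, used)[0],
            _random_barcodes(rng, 1, used)[0],
        )
        for w in wells
    }
    contaminated = [
        wells[i]
        for i in rng.choice(len(wells), size=n_contaminated_wells, replace=False)
    ]
    n_contam = int(round(contamination_fraction * n_reads_per_well))

    reads: list[tuple[str, str]] = []
    for w in wells:
        plate, row, col = w
        tag_seq = scheme.plate_tags[plate] + scheme.row_tags[row] + scheme.col_tags[col]
        clones = [(truth[w], n_reads_per_well)]
        if w in contaminated:
            donor = wells[int(rng.integers(0, len(wells)))]
            while donor == w:
                donor = wells[int(rng.integers(0, len(wells)))]
            clones = [(truth[w], n_reads_per_well - n_contam), (truth[donor], n_contam)]
        for (bc1, bc2), n in clones:
            body = bc1 + scheme.linker + bc2
            for k in range(n):
                t = list(tag_seq)
                for pos in range(len(t)):
                    if rng.random() < tag_error_rate:
                        t[pos] = "ACGT"[int(rng.integers(0, 4))]
                reads.append((f"{plate}:{row}:{col}:{k}", "".join(t) + body))
    return reads, scheme, truth, contaminated
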