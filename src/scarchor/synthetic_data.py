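"""Forward simulator of replication-coupled histone segregation.

Generates everything the analysis pipeline consumes: a genome with regularly
spaced replication initiation zones (IZs) and repressive-mark domains,
nucleosome-level parental-histone segregation behind replication forks, and
the resulting stranded IP/input read sets (with constant-proportion spike-in
chromatin) plus peptidoform MS tables.

Model
-----
Replication forks move outward from each IZ midpoint; the leading nascent
strand maps to the forward genome strand on the rightward-moving side and to
the reverse strand on the leftward side. Each parental nucleosome at a
replicated position is either

* recycled in place to the leading daughter (probability ``p_lead`` among
  non-evicted histones) or the lagging daughter,
* or evicted (probability ``evict_frac``), in which case it is redeposited
  onto another nascent slot (probability ``redeposit_frac``; random strand,
  optionally restricted to non-domain positions) or lost to the soluble
  pool.

Every daughter slot not occupied by a parental histone is filled by a new
histone, so nucleosome density is conserved. Parental histones carry
H4K20me2 (and H3K27me3 iff their position of origin lies in a mark domain);
new histones carry H4K20me0 and no H3K27me3. Redeposited histones retain
their marks by default.

SCAR-seq sampling is restricted to the nascent (EdU-labeled) windows around
IZs where fork directionality is defined; ChOR-seq sampling treats the whole
genome as replicated, since its quantification is strand-blind. Spike-in
chromatin is a constant proportion of total chromatin; spike read counts are
set to their expected values rather than resampled, so that desk-scale read
depths do not inject calibration noise into the spike channel.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_io import (
    FORWARD,
    REVERSE,
    GenomeLayout,
    IntervalSet,
    make_read_frame,
    write_intervals,
    write_reads_bed6,
)
from .iz_metaprofile import InitiationZoneSet

# RNG stream ids (offsets on the user seed) so each library draws from an
# independent, reproducible stream
_STREAMS = {
    "scar_ip": 1,
    "scar_input": 2,
    "chor_ctrl": 3,
    "chor_treat": 4,
    "chor_input_ctrl": 5,
    "chor_input_treat": 6,
    "ms": 7,
    "landscape": 8,
    "scar_fates": 9,
    "scar_ip_new": 10,
}


def _rng(cfg: "SimConfig", stream: str, sub: int = 0) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAMS[stream], sub])


@dataclass(frozen=True)
class SimConfig:
    """Full generative parameterization of one simulated condition."""

    # genome layout
    n_chroms: int = 8
    chrom_length: int = 20_000_000
    iz_spacing: int = 20_000_000
    nucleosome_spacing: int = 200
    domain_width: int = 40_000
    domain_spacing: int = 400_000
    nascent_span: int = 310_000  # EdU-labeled span each side of an IZ (SCAR)
    # segregation model
    p_lead: float = 0.5
    evict_frac: float = 0.0
    redeposit_frac: float = 0.0
    redeposit_target: str = "outside_domains"  # or "uniform"
    retain_marks_on_redeposit: bool = True
    # libraries
    ip_depth: int = 2_000_000
    input_depth: int = 1_000_000
    fragment_len: int = 150
    spike_fraction: float = 0.0005  # spike chromatin / total chromatin
    spike_mark_prevalence: float = 0.5
    spike_prefix: str = "dm6_"
    spike_chrom_length: int = 1_000_000
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("p_lead", "evict_frac", "redeposit_frac", "spike_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.iz_spacing >= 2 * self.chrom_length:
            raise ValueError("iz_spacing must place at least one IZ per chromosome")
        if self.nascent_span > self.iz_spacing // 2:
            raise ValueError("nascent_span must not reach the neighboring IZ basin")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


PRESETS: dict[str, dict] = {
    # wild type: symmetric recycling, no eviction
    "wt": dict(p_lead=0.50, evict_frac=0.0, redeposit_frac=0.0),
    # POLE4 depletion alone: moderate lagging-strand bias, no loss
    "dpole4": dict(p_lead=0.42, evict_frac=0.0, redeposit_frac=0.0),
    # MCM2-2A: strong leading-strand bias, no loss
    "mcm2-2a": dict(p_lead=0.85, evict_frac=0.0, redeposit_frac=0.0),
    # POLE4 depletion in MCM2-2A: leading bias plus eviction; a quarter of
    # evicted histones are redeposited elsewhere (outside mark domains), the
    # rest are lost to the soluble pool -> 20% in-domain / 15% genome-wide loss
    "dpole4-mcm2-2a": dict(
        p_lead=0.80, evict_frac=0.20, redeposit_frac=0.25,
        redeposit_target="outside_domains",
    ),
}


def get_preset(name: str) -> SimConfig:
    """Named study conditions; all share spike_fraction 0.0005."""
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    return SimConfig(**PRESETS[name])


@dataclass
class Landscape:
    layout: GenomeLayout
    izs: InitiationZoneSet
    domains: IntervalSet
    spike_chrom: str = "dm6_chr2L"
    spike_chrom_length: int = 1_000_000


@dataclass(frozen=True)
class NucleosomeState:
    """One nucleosome on one daughter strand (conceptual unit of the model)."""

    chrom: str
    position: int
    daughter_strand: str  # "leading" or "lagging"
    histone_class: str    # "parental", "new", or "redeposited"
    marks: frozenset[str]


def build_landscape(cfg: SimConfig) -> Landscape:
    """Deterministic genome: chromosomes, IZ grid, non-overlapping domains.

    IZ midpoints sit at spacing/2, 3*spacing/2, ... on every chromosome;
    forks terminate midway between adjacent midpoints (and at chromosome
    ends). Domains are tiled at ``domain_spacing`` with a seeded, 1-kb
    aligned phase offset per chromosome.
    """
    chrom_sizes = {
        f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)
    }
    layout = GenomeLayout(chrom_sizes, spike_prefix=cfg.spike_prefix)
    rng = _rng(cfg, "landscape")
    iz_rows, dom_rows = [], []
    half_iz = 1000
    for chrom in chrom_sizes:
        mids = np.arange(cfg.iz_spacing // 2, cfg.chrom_length, cfg.iz_spacing)
        for m in mids:
            iz_rows.append((chrom, int(m) - half_iz, int(m) + half_iz))
        max_phase = max(1, (cfg.domain_spacing - cfg.domain_width) // 1000)
        phase = int(rng.integers(0, max_phase)) * 1000
        starts = np.arange(phase, cfg.chrom_length - cfg.domain_width,
                           cfg.domain_spacing)
        for s in starts:
            dom_rows.append((chrom, int(s), int(s) + cfg.domain_width))
    izs = InitiationZoneSet(
        IntervalSet(pd.DataFrame(iz_rows, columns=["chrom", "start", "end"]))
    )
    domains = IntervalSet(pd.DataFrame(dom_rows, columns=["chrom", "start", "end"]))
    return Landscape(layout, izs, domains,
                     spike_chrom=f"{cfg.spike_prefix}chr2L",
                     spike_chrom_length=cfg.spike_chrom_length)


def fork_direction(landscape: Landscape, chrom: str, pos: np.ndarray) -> np.ndarray:
    """+1 where the fork moves rightward (pos at/right of its IZ midpoint),
    -1 where it moves leftward. Each position belongs to the basin of its
    nearest IZ midpoint; direction flips only at midpoints and at
    termination points midway between adjacent IZs."""
    mids = landscape.izs.midpoints
    mids = mids.loc[mids["chrom"] == chrom, "midpoint"].to_numpy()
    if len(mids) == 0:
        raise ValueError(f"no IZ on chromosome {chrom}")
    pos = np.asarray(pos)
    nearest = mids[np.argmin(np.abs(pos[:, None] - mids[None, :]), axis=1)]
    return np.where(pos >= nearest, 1, -1)


def _in_intervals(pos: np.ndarray, ivs: IntervalSet, chrom: str) -> np.ndarray:
    """Boolean membership of positions in a chromosome's intervals."""
    df = ivs.df[ivs.df["chrom"] == chrom]
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    i = np.searchsorted(starts, pos, side="right") - 1
    ok = i >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = pos[ok] < ends[i[ok]]
    return out


def _segregate(
    cfg: SimConfig,
    rng: np.random.Generator,
    chroms: np.ndarray,
    positions: np.ndarray,
    direction: np.ndarray,
    in_domain: np.ndarray,
    domain_free: np.ndarray,
) -> dict:
    """Assign parental fates and fill daughter slots for given positions.

    ``domain_free`` flags positions eligible as redeposition targets under
    the 'outside_domains' rule. Returns slot-level arrays plus exact
    conservation counts.
    """
    n = len(positions)
    u = rng.random(n)
    evicted = u < cfg.evict_frac
    recycled = ~evicted
    lead = np.zeros(n, dtype=bool)
    lead[recycled] = rng.random(recycled.sum()) < cfg.p_lead
    redep_src = evicted & (rng.random(n) < cfg.redeposit_frac)
    lost = evicted & ~redep_src

    # daughter slot occupancy: column 0 = forward strand, 1 = reverse strand
    occ = np.zeros((n, 2), dtype=bool)
    # rightward fork: leading daughter is the forward strand
    strand_col = np.where(
        (direction > 0) == lead[: n], 0, 1
    )
    occ[np.nonzero(recycled)[0], strand_col[recycled]] = True
    parental_slot_pos = positions[recycled]
    parental_slot_chrom = chroms[recycled]
    parental_slot_strand = np.where(strand_col[recycled] == 0, FORWARD, REVERSE)
    parental_origin_in_domain = in_domain[recycled]

    # redeposition: evicted histones rebind free nascent slots on a random
    # strand, optionally only outside domains
    n_redep = int(redep_src.sum())
    redep_pos = np.empty(0, dtype=positions.dtype)
    redep_chrom = np.empty(0, dtype=chroms.dtype)
    redep_strand = np.empty(0, dtype="<U1")
    redep_origin_in_domain = in_domain[redep_src]
    if n_redep:
        eligible_pos = (
            domain_free if cfg.redeposit_target == "outside_domains"
            else np.ones(n, dtype=bool)
        )
        # strand drawn fairly first (the free-slot pool itself is biased
        # toward the lagging strand), then a free slot on that strand
        n_fwd = int(rng.binomial(n_redep, 0.5))
        rows_list, cols_list = [], []
        for col, k in ((0, n_fwd), (1, n_redep - n_fwd)):
            free_rows = np.nonzero(~occ[:, col] & eligible_pos)[0]
            chosen = rng.choice(free_rows, size=k, replace=False)
            occ[chosen, col] = True
            rows_list.append(chosen)
            cols_list.append(np.full(k, col))
        rows = np.concatenate(rows_list)
        cols = np.concatenate(cols_list)
        redep_pos = positions[rows]
        redep_chrom = chroms[rows]
        redep_strand = np.where(cols == 0, FORWARD, REVERSE)

    free = ~occ  # slots filled by new histones
    new_rows, new_cols = np.nonzero(free)
    return {
        "occ": occ,
        "parental": dict(
            chrom=parental_slot_chrom, pos=parental_slot_pos,
            strand=parental_slot_strand, in_domain=parental_origin_in_domain,
        ),
        "redeposited": dict(
            chrom=redep_chrom, pos=redep_pos, strand=redep_strand,
            origin_in_domain=redep_origin_in_domain,
        ),
        "new": dict(
            chrom=chroms[new_rows], pos=positions[new_rows],
            strand=np.where(new_cols == 0, FORWARD, REVERSE),
        ),
        "counts": dict(
            parental=int(n),
            recycled_leading=int(lead.sum()),
            recycled_lagging=int((recycled & ~lead).sum()),
            evicted=int(evicted.sum()),
            redeposited=n_redep,
            lost_to_soluble=int(lost.sum()),
        ),
    }


def _sample_reads(
    cfg: SimConfig,
    rng: np.random.Generator,
    chrom: np.ndarray,
    pos: np.ndarray,
    strand: np.ndarray,
    n_reads: int,
) -> pd.DataFrame:
    """Sample reads (with replacement) from weighted-1 nucleosome slots."""
    if len(pos) == 0 or n_reads == 0:
        return make_read_frame([], [], [], [], [])
    idx = rng.integers(0, len(pos), size=n_reads)
    centers = pos[idx]
    start = np.maximum(centers - cfg.fragment_len // 2, 0)
    return make_read_frame(
        chrom[idx], start, start + cfg.fragment_len, strand[idx], "target"
    )


def _spike_reads(
    cfg: SimConfig, rng: np.random.Generator, landscape: Landscape, n: int
) -> pd.DataFrame:
    if n == 0:
        return make_read_frame([], [], [], [], [])
    start = rng.integers(0, landscape.spike_chrom_length - cfg.fragment_len, size=n)
    strand = np.where(rng.random(n) < 0.5, FORWARD, REVERSE)
    return make_read_frame(
        np.repeat(landscape.spike_chrom, n), start, start + cfg.fragment_len,
        strand, "spike",
    )


def _nascent_positions(cfg: SimConfig, landscape: Landscape):
    """Nucleosome positions in the EdU windows around every IZ."""
    chroms, positions, direction = [], [], []
    for iz in landscape.izs.midpoints.itertuples(index=False):
        size = landscape.layout.chrom_sizes[iz.chrom]
        lo = max(0, iz.midpoint - cfg.nascent_span)
        hi = min(size, iz.midpoint + cfg.nascent_span)
        p = np.arange(lo, hi, cfg.nucleosome_spacing, dtype=np.int64)
        chroms.append(np.repeat(iz.chrom, len(p)))
        positions.append(p)
        direction.append(np.where(p >= iz.midpoint, 1, -1))
    return (
        np.concatenate(chroms),
        np.concatenate(positions),
        np.concatenate(direction),
    )


def _domain_flags(landscape: Landscape, chroms: np.ndarray, pos: np.ndarray):
    in_domain = np.zeros(len(pos), dtype=bool)
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        in_domain[sel] = _in_intervals(pos[sel], landscape.domains, chrom)
    return in_domain


def segregate_and_sample_scar(
    cfg: SimConfig, landscape: Landscape, mark: str = "H4K20me2"
) -> tuple[pd.DataFrame, dict]:
    """Simulate one SCAR-seq IP library for a parental or new-histone mark.

    ``mark`` is 'H4K20me2' (parental histones: recycled + redeposited) or
    'H4K20me0' (new histones). Reads are fragment_len intervals centered on
    nucleosomes in the nascent windows, on the genomic strand of their
    daughter slot. Returns the read frame and an exact truth record.
    """
    if mark not in ("H4K20me2", "H4K20me0"):
        raise ValueError("mark must be 'H4K20me2' or 'H4K20me0'")
    chroms, positions, direction = _nascent_positions(cfg, landscape)
    in_domain = _domain_flags(landscape, chroms, positions)
    fates = _segregate(
        cfg, _rng(cfg, "scar_fates"), chroms, positions, direction,
        in_domain, ~in_domain,
    )
    n_spike = int(round(cfg.ip_depth * cfg.spike_fraction))
    n_target = cfg.ip_depth - n_spike
    rng = _rng(cfg, "scar_ip" if mark == "H4K20me2" else "scar_ip_new")
    if mark == "H4K20me2":
        pool_chrom = np.concatenate(
            [fates["parental"]["chrom"], fates["redeposited"]["chrom"]]
        )
        pool_pos = np.concatenate(
            [fates["parental"]["pos"], fates["redeposited"]["pos"]]
        )
        pool_strand = np.concatenate(
            [fates["parental"]["strand"], fates["redeposited"]["strand"]]
        )
    else:
        pool_chrom = fates["new"]["chrom"]
        pool_pos = fates["new"]["pos"]
        pool_strand = fates["new"]["strand"]
    reads = pd.concat(
        [
            _sample_reads(cfg, rng, pool_chrom, pool_pos, pool_strand, n_target),
            _spike_reads(cfg, rng, landscape, n_spike),
        ],
        ignore_index=True,
    )
    truth = dict(fates["counts"])
    truth["mark"] = mark
    truth["n_marked_slots"] = int(len(pool_pos))
    truth["n_target_reads"] = n_target
    truth["n_spike_reads"] = n_spike
    return reads, truth


def simulate_input(
    cfg: SimConfig, landscape: Landscape, stream: str = "scar_input"
) -> pd.DataFrame:
    """Matched input: uniform positions genome-wide, Bernoulli(0.5) strand,
    spike reads at the constant chromatin proportion."""
    rng = _rng(cfg, stream)
    n_spike = int(round(cfg.input_depth * cfg.spike_fraction))
    n_target = cfg.input_depth - n_spike
    sizes = landscape.layout.chrom_sizes
    names = list(sizes)
    total = sum(sizes.values())
    weights = np.array([sizes[c] for c in names], dtype=float) / total
    chrom_idx = rng.choice(len(names), size=n_target, p=weights)
    lens = np.array([sizes[c] for c in names])
    start = (rng.random(n_target) * (lens[chrom_idx] - cfg.fragment_len)).astype(np.int64)
    strand = np.where(rng.random(n_target) < 0.5, FORWARD, REVERSE)
    target = make_read_frame(
        np.array(names, dtype=object)[chrom_idx], start,
        start + cfg.fragment_len, strand, "target",
    )
    return pd.concat(
        [target, _spike_reads(cfg, rng, landscape, n_spike)], ignore_index=True
    )


def _genome_positions(cfg: SimConfig, landscape: Landscape):
    chroms, positions = [], []
    for chrom, size in landscape.layout.chrom_sizes.items():
        p = np.arange(0, size, cfg.nucleosome_spacing, dtype=np.int64)
        chroms.append(np.repeat(chrom, len(p)))
        positions.append(p)
    return np.concatenate(chroms), np.concatenate(positions)


def _simulate_chor_library(
    cfg: SimConfig, landscape: Landscape, mark: str, stream: str
) -> tuple[pd.DataFrame, dict]:
    """One ChOR IP library: whole-genome replication, strandless quant."""
    chroms, positions = _genome_positions(cfg, landscape)
    in_domain = _domain_flags(landscape, chroms, positions)
    direction = np.ones(len(positions), dtype=np.int64)
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        direction[sel] = fork_direction(landscape, chrom, positions[sel])
    fates = _segregate(
        cfg, _rng(cfg, stream, sub=0), chroms, positions, direction,
        in_domain, ~in_domain,
    )
    if mark == "H3K27me3" or mark == "H3K36me3":
        par = fates["parental"]
        red = fates["redeposited"]
        keep_par = par["in_domain"]
        keep_red = (
            red["origin_in_domain"]
            if cfg.retain_marks_on_redeposit
            else np.zeros(len(red["pos"]), dtype=bool)
        )
        pool_chrom = np.concatenate([par["chrom"][keep_par], red["chrom"][keep_red]])
        pool_pos = np.concatenate([par["pos"][keep_par], red["pos"][keep_red]])
        pool_strand = np.concatenate(
            [par["strand"][keep_par], red["strand"][keep_red]]
        )
        n_marked_in_domain = int(
            _domain_sum(landscape, pool_chrom, pool_pos)
        )
    elif mark == "H3":
        parts = [fates["parental"], fates["redeposited"], fates["new"]]
        pool_chrom = np.concatenate([p["chrom"] for p in parts])
        pool_pos = np.concatenate([p["pos"] for p in parts])
        pool_strand = np.concatenate([p["strand"] for p in parts])
        n_marked_in_domain = int(_domain_sum(landscape, pool_chrom, pool_pos))
    else:
        raise ValueError("ChOR mark must be 'H3K27me3', 'H3K36me3', or 'H3'")

    # spike chromatin: constant proportion of total chromatin, constant mark
    # prevalence; IP spike reads at the expected composition
    total_chromatin = 2 * len(positions)
    spike_marked_mass = (
        cfg.spike_fraction * total_chromatin * cfg.spike_mark_prevalence
    )
    mouse_marked_mass = float(len(pool_pos))
    spike_share = spike_marked_mass / (spike_marked_mass + mouse_marked_mass)
    n_spike = int(round(cfg.ip_depth * spike_share))
    n_target = cfg.ip_depth - n_spike
    rng = _rng(cfg, stream, sub=1)
    reads = pd.concat(
        [
            _sample_reads(cfg, rng, pool_chrom, pool_pos, pool_strand, n_target),
            _spike_reads(cfg, rng, landscape, n_spike),
        ],
        ignore_index=True,
    )
    truth = dict(fates["counts"])
    truth.update(
        mark=mark,
        marked_mass_total=mouse_marked_mass,
        marked_mass_in_domain=n_marked_in_domain,
        spike_marked_mass=spike_marked_mass,
        n_target_reads=n_target,
        n_spike_reads=n_spike,
    )
    return reads, truth


def _domain_sum(landscape: Landscape, chroms: np.ndarray, pos: np.ndarray) -> int:
    return int(_domain_flags(landscape, chroms, pos).sum())


def simulate_chor_pair(
    cfg_ctrl: SimConfig, cfg_treat: SimConfig, mark: str = "H3K27me3"
) -> dict:
    """Paired ChOR libraries (IP + matched input per condition) plus truth.

    Both configs must share the same spike fraction and genome layout; the
    landscape is built from the control config.
    """
    if cfg_ctrl.spike_fraction != cfg_treat.spike_fraction:
        raise ValueError("spike_fraction must be identical across conditions")
    landscape = build_landscape(cfg_ctrl)
    ip_c, truth_c = _simulate_chor_library(cfg_ctrl, landscape, mark, "chor_ctrl")
    ip_t, truth_t = _simulate_chor_library(cfg_treat, landscape, mark, "chor_treat")
    input_c = simulate_input(cfg_ctrl, landscape, "chor_input_ctrl")
    input_t = simulate_input(cfg_treat, landscape, "chor_input_treat")
    truth = {
        "control": truth_c,
        "treated": truth_t,
        "retention_in_domain": truth_t["marked_mass_in_domain"]
        / truth_c["marked_mass_in_domain"],
        "retention_genome_wide": truth_t["marked_mass_total"]
        / truth_c["marked_mass_total"],
    }
    return {
        "landscape": landscape,
        "ip": {"control": ip_c, "treated": ip_t},
        "input": {"control": input_c, "treated": input_t},
        "truth": truth,
    }


def simulate_ms_table(
    truth_percent: dict[str, dict[str, float]],
    noise_cv: float = 0.0,
    seed: int = 0,
    base_area: float = 1e6,
) -> dict:
    """Peptidoform MS1 areas from ground-truth site-state percentages.

    ``truth_percent`` maps a backbone_id to {state_token: percent} summing
    to 100 per backbone. Areas are proportional to the truth with
    multiplicative lognormal noise of coefficient of variation ``noise_cv``.
    Also emits one isobaric pair (true 3:1 split) with consistent fragment
    ratios for exercising the MS2-based deconvolution.
    """
    rng = np.random.default_rng([seed, _STREAMS["ms"]])
    sigma = np.sqrt(np.log1p(noise_cv**2))
    rows = []
    for backbone, states in truth_percent.items():
        total = sum(states.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"{backbone}: state percentages sum to {total}, not 100")
        for state, pct in states.items():
            noise = float(np.exp(rng.normal(0.0, sigma) - sigma**2 / 2)) if sigma else 1.0
            rows.append((backbone, state, 2, base_area * pct / 100.0 * noise))
    table = pd.DataFrame(
        rows, columns=["backbone_id", "modset", "charge", "ms1_area"]
    )
    table["modset"] = table["modset"].map(lambda s: frozenset(s.split(";")))
    from .ms_ptm import FragmentPairSet

    true_a, true_b = 0.75 * base_area, 0.25 * base_area
    pairs = FragmentPairSet(
        [("y7", 300.0, 100.0), ("y5", 60.0, 20.0), ("b3", 150.0, 50.0)]
    )
    return {
        "table": table,
        "isobaric": {
            "total_area": true_a + true_b,
            "pairs": pairs,
            "true_areas": (true_a, true_b),
        },
    }


def write_sim_outputs(cfg: SimConfig, outdir: str) -> dict:
    """Emit one preset's full SCAR input set as plain-text files.

    Writes per-library BED6 reads, iz.bed, domains.bed and truth.json;
    returns the truth record. All outputs are deterministic for a given
    config (byte-for-byte).
    """
    os.makedirs(outdir, exist_ok=True)
    landscape = build_landscape(cfg)
    truth: dict = {"config": dataclasses.asdict(cfg)}
    for mark in ("H4K20me2", "H4K20me0"):
        reads, t = segregate_and_sample_scar(cfg, landscape, mark)
        write_reads_bed6(reads, os.path.join(outdir, f"{mark}.ip.bed"))
        truth[mark] = t
    inp = simulate_input(cfg, landscape)
    write_reads_bed6(inp, os.path.join(outdir, "input.bed"))
    write_intervals(landscape.izs.intervals, os.path.join(outdir, "iz.bed"))
    write_intervals(landscape.domains, os.path.join(outdir, "domains.bed"))
    sizes_path = os.path.join(outdir, "genome.sizes.tsv")
    with open(sizes_path, "w") as fh:
        for chrom, size in landscape.layout.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
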