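"""End-to-end simulated studies wiring the simulator to the analysis stack.

These are the entry points the ``reproduce`` command and the acceptance
script use: simulate a preset, run the full partition pipeline, orient to
the simulated IZs, and report the leading-strand fraction; or simulate a
paired ChOR experiment and report spike-in-calibrated recycling-efficiency
changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .chor_quant import (
    SpikeCounts,
    efficiency_change,
    global_spike_ratio,
    quantify_peak_windows,
    rrpm_track,
)
from .genomic_io import ReadTally
from .iz_metaprofile import leading_fraction, metaprofile, orient_to_iz
from .scar_partition import partition_pipeline
from .synthetic_data import (
    Landscape,
    SimConfig,
    build_landscape,
    get_preset,
    segregate_and_sample_scar,
    simulate_chor_pair,
    simulate_input,
)


def _tally(reads: pd.DataFrame) -> ReadTally:
    origin = reads["origin"]
    return ReadTally(
        target=int((origin == "target").sum()),
        spike=int((origin == "spike").sum()),
    )


def scar_study(
    cfg: SimConfig,
    mark: str = "H4K20me2",
    bin_width: int = 1000,
    blur_half_width: int = 30,
    min_cpm: float = 0.3,
    flank: int = 250_000,
) -> dict:
    """Simulate one SCAR library pair and quantify histone segregation.

    Returns the leading-strand fraction report, the metaprofile, and the
    oriented-window table for further statistics.
    """
    landscape = build_landscape(cfg)
    ip_reads, truth = segregate_and_sample_scar(cfg, landscape, mark)
    input_reads = simulate_input(cfg, landscape)
    ptrack = partition_pipeline(
        ip_reads.loc[ip_reads["origin"] == "target"],
        input_reads.loc[input_reads["origin"] == "target"],
        landscape.layout,
        bin_width=bin_width,
        blur_half_width=blur_half_width,
        min_cpm=min_cpm,
    )
    table = orient_to_iz(ptrack, landscape.izs, flank=flank)
    frac = leading_fraction(
        table, min_abs_offset_bins=blur_half_width + 1, seed=cfg.seed
    )
    return {
        "mark": mark,
        "truth": truth,
        "partition": ptrack,
        "oriented_windows": table,
        "metaprofile": metaprofile(table),
        "leading_fraction": frac,
    }


def scar_preset_study(preset: str, seed: int, mark: str = "H4K20me2", **kwargs) -> dict:
    cfg = get_preset(preset).replace(seed=seed)
    out = scar_study(cfg, mark=mark, **kwargs)
    out["preset"] = preset
    return out


def chor_efficiency_study(
    cfg_ctrl: SimConfig,
    cfg_treat: SimConfig,
    mark: str = "H3K27me3",
    bin_width: int = 1000,
) -> dict:
    """Simulate a paired ChOR experiment; quantify RRPM efficiency changes.

    Reports percent signal loss in treated vs control within cognate mark
    domains (1-kb bins overlapping domains) and genome-wide, plus the
    spike-ratio bar-plot statistics.
    """
    sim = simulate_chor_pair(cfg_ctrl, cfg_treat, mark)
    landscape: Landscape = sim["landscape"]
    tracks, ratios = {}, {}
    for cond in ("control", "treated"):
        counts = SpikeCounts.from_tallies(
            _tally(sim["ip"][cond]), _tally(sim["input"][cond])
        )
        tracks[cond] = rrpm_track(
            sim["ip"][cond], landscape.layout, counts, bin_width=bin_width
        )
        ratios[cond] = global_spike_ratio(counts)
    dom_t = quantify_peak_windows(tracks["treated"], landscape.domains)
    dom_c = quantify_peak_windows(tracks["control"], landscape.domains)
    return {
        "mark": mark,
        "truth": sim["truth"],
        "tracks": tracks,
        "global_spike_ratio": ratios,
        "efficiency_in_domain": efficiency_change(dom_t, dom_c, "in_domain"),
        "efficiency_genome_wide": efficiency_change(
            tracks["treated"].total(), tracks["control"].total(), "genome_wide"
        ),
    }


def chor_preset_study(
    control_preset: str = "mcm2-2a",
    treated_preset: str = "dpole4-mcm2-2a",
    seed: int = 1,
    mark: str = "H3K27me3",
    **kwargs,
) -> dict:
    cfg_c = get_preset(control_preset).replace(seed=seed)
    cfg_t = get_preset(treated_preset).replace(seed=seed)
    out = chor_efficiency_study(cfg_c, cfg_t, mark=mark, **kwargs)
    out["control_preset"] = control_preset
    out["treated_preset"] = treated_preset
    return out


#: expected leading-strand percentages per preset (wt/dpole4-mcm2-2a are the
#: quantitative claims the simulator is built to reproduce; dpole4/mcm2-2a
#: are the package's own design values)
EXPECTED_LEADING = {
    "wt": (50.0, 1.0),
    "dpole4": (42.0, 2.0),
    "mcm2-2a": (85.0, 2.0),
    "dpole4-mcm2-2a": (80.0, 2.0),
}


def reproduce_report(seed: int = 1) -> dict:
    """Run the full simulated study: all four presets through the SCAR
    partition pipeline (both marks) and the ChOR efficiency comparison.

    Returns a JSON-serializable report; ``all_within_tolerance`` is True iff
    every recovered value matches its expectation at the stated tolerance
    (leading fractions as above; 20 +/- 2 in-domain and 15 +/- 2 genome-wide
    percent efficiency loss).
    """
    report: dict = {"seed": seed, "scar": {}, "chor": {}}
    ok = True
    for preset, (expected, tol) in EXPECTED_LEADING.items():
        entry: dict = {}
        for mark in ("H4K20me2", "H4K20me0"):
            study = scar_preset_study(preset, seed, mark=mark)
            entry[mark] = {
                "leading_fraction_percent": study["leading_fraction"]["percent"],
                "ci": [
                    study["leading_fraction"]["ci_low"],
                    study["leading_fraction"]["ci_high"],
                ],
                "n_windows": study["leading_fraction"]["n_windows"],
            }
        got = entry["H4K20me2"]["leading_fraction_percent"]
        entry["expected_percent"] = expected
        entry["tolerance"] = tol
        entry["within_tolerance"] = bool(abs(got - expected) <= tol)
        ok = ok and entry["within_tolerance"]
        report["scar"][preset] = entry
    chor = chor_preset_study(seed=seed)
    chor_entry = {
        "control_preset": chor["control_preset"],
        "treated_preset": chor["treated_preset"],
        "efficiency_in_domain_percent": chor["efficiency_in_domain"],
        "efficiency_genome_wide_percent": chor["efficiency_genome_wide"],
        "global_spike_ratio": chor["global_spike_ratio"],
        "truth_retention_in_domain": chor["truth"]["retention_in_domain"],
        "truth_retention_genome_wide": chor["truth"]["retention_genome_wide"],
        "expected": {"in_domain": 20.0, "genome_wide": 15.0},
        "tolerance": 2.0,
    }
    chor_entry["within_tolerance"] = bool(
        abs(chor_entry["efficiency_in_domain_percent"] - 20.0) <= 2.0
        and abs(chor_entry["efficiency_genome_wide_percent"] - 15.0) <= 2.0
    )
    ok = ok and chor_entry["within_tolerance"]
    report["chor"]["H3K27me3"] = chor_entry
    report["all_within_tolerance"] = ok
    return report
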