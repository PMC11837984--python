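"""Histone-PTM relative abundance from bottom-up MS peptidoform areas.

Quantification starts from a table of MS1 areas per peptidoform (a specific
combination of modifications on one peptide backbone, e.g. H3 18-26 with
K18ac,K23un). The relative abundance of a mark is the summed area of all
peptidoforms carrying it divided by the total area of that backbone, in
percent; charge states are summed. Coeluting isobaric peptidoform pairs
(e.g. H3K36me3 vs H3K27me2K36me1) are split by the averaged ratio of
analogous MS2 fragment ions before abundance calculation.

Input table columns (TSV): backbone_id, modset (semicolon-separated
site:state tokens such as "K27me3;K36un"), charge, ms1_area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TABLE_COLUMNS = ["backbone_id", "modset", "charge", "ms1_area"]


@dataclass(frozen=True)
class PeptidoformRecord:
    backbone_id: str
    modset: frozenset[str]
    ms1_area: float
    charge: int = 2

    def __post_init__(self) -> None:
        if self.ms1_area < 0:
            raise ValueError("ms1_area must be nonnegative")


@dataclass
class FragmentPairSet:
    """Analogous MS2 fragment intensities for two coeluting species a, b."""

    pairs: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for label, ia, ib in self.pairs:
            if ia < 0 or ib < 0:
                raise ValueError(f"negative fragment intensity for ion {label}")


def resolve_isobaric(
    total_area: float, pairs: FragmentPairSet, mean: str = "arithmetic"
) -> tuple[float, float]:
    """Split a pooled isobaric MS1 area between two coeluting species.

    The averaged per-ion intensity ratio r = mean(I_a/I_b) fixes the split
    area_a = total*r/(1+r), area_b = total - area_a, so the two areas sum
    to the pooled area exactly. ``mean`` selects arithmetic (default) or
    geometric averaging of the per-ion ratios.
    """
    if total_area < 0:
        raise ValueError("total_area must be nonnegative")
    ratios = [ia / ib for _, ia, ib in pairs.pairs if ib > 0]
    if not ratios:
        warnings.warn(
            "no fragment pair with nonzero b intensity; assigning full area to a",
            stacklevel=2,
        )
        return total_area, 0.0
    if mean == "arithmetic":
        r = float(np.mean(ratios))
    elif mean == "geometric":
        r = float(np.exp(np.mean(np.log(ratios))))
    else:
        raise ValueError("mean must be 'arithmetic' or 'geometric'")
    area_a = total_area * r / (1.0 + r)
    return area_a, total_area - area_a


def _parse_modset(s: str) -> frozenset[str]:
    return frozenset(tok.strip() for tok in str(s).split(";") if tok.strip())


def read_peptidoform_table(path: str) -> pd.DataFrame:
    """Read a peptidoform area TSV; modset parsed to frozensets."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peptidoform table missing columns {missing}")
    df = df.copy()
    df["modset"] = df["modset"].map(_parse_modset)
    if (df["ms1_area"] < 0).any():
        raise ValueError("negative ms1_area in table")
    return df


def relative_abundance(records: pd.DataFrame, target: str) -> float | None:
    """Percent of a backbone's total MS1 area carried by one site state.

    ``records`` must all share the backbone containing the target site (a
    token such as "K27me3"). Charge states are summed implicitly. Returns
    None when the backbone has zero total area (missing, not 0%).
    """
    backbones = records["backbone_id"].unique()
    if len(backbones) > 1:
        raise ValueError(f"records span multiple backbones: {list(backbones)}")
    total = float(records["ms1_area"].sum())
    if total == 0:
        return None
    has_target = records["modset"].map(lambda m: target in m)
    return 100.0 * float(records.loc[has_target, "ms1_area"].sum()) / total


def site_state_vector(records: pd.DataFrame, site: str) -> dict[str, float | None]:
    """Relative abundance of every observed state of one site (e.g. K27).

    States are the tokens starting with ``site`` across the backbone's
    modsets (K27un, K27me1, ...). Over the exhaustive state set the values
    sum to 100%.
    """
    states = sorted(
        {tok for mods in records["modset"] for tok in mods if tok.startswith(site)}
    )
    return {state: relative_abundance(records, state) for state in states}


def abundance_report(table: pd.DataFrame, sites: dict[str, str]) -> pd.DataFrame:
    """Per-mark relative abundances for the requested sites.

    ``sites`` maps a site token (e.g. "K27") to its backbone_id. Returns a
    tidy frame (site, state, percent); missing backbones yield NaN.
    """
    rows = []
    for site, backbone in sites.items():
        sub = table[table["backbone_id"] == backbone]
        if len(sub) == 0:
            rows.append((site, None, np.nan))
            continue
        for state, pct in site_state_vector(sub, site).items():
            rows.append((site, state, np.nan if pct is None else pct))
    return pd.DataFrame(rows, columns=["site", "state", "percent"])
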