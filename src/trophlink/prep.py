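"""Isotope preprocessing: δ notation, lipid correction, spatial baseline
correction, trophic levels, proportional nitrogen TEF, and functional-group
summaries.

Pipeline order is lipid correction first, then baseline correction (both act
on δ13C; the lipid correction is a within-sample chemistry adjustment while
the baseline correction is a between-station normalisation, so the order only
matters for bookkeeping and is configurable in the pipeline).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GroupSummary, TefModel

logger = logging.getLogger(__name__)

#: C:N ratio above which muscle tissue is considered lipid-rich enough to bias δ13C
LIPID_CN_THRESHOLD = 3.5


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Isotope ratio to δ notation in per-mil: (R_sample/R_standard − 1)·10³."""
    if r_standard <= 0:
        raise ValueError("r_standard must be > 0")
    return (r_sample / r_standard - 1.0) * 1e3


def ratio_from_delta(delta: float, r_standard: float) -> float:
    """Inverse of :func:`delta_from_ratio`."""
    if r_standard <= 0:
        raise ValueError("r_standard must be > 0")
    return (delta / 1e3 + 1.0) * r_standard


def lipid_correct(d13c: float, c_to_n: float) -> float:
    """Mathematical lipid normalisation of δ13C for lipid-rich tissue.

    Applied only when C:N strictly exceeds 3.5; equality is left untouched:
    δ13C' = δ13C − 3.32 + 0.99 · C:N.
    """
    if c_to_n < 0:
        raise ValueError("C:N ratio must be >= 0")
    if c_to_n > LIPID_CN_THRESHOLD:
        return d13c - 3.32 + 0.99 * c_to_n
    return d13c


def baseline_correct(value: float, local_baseline: float, mean_baseline: float) -> float:
    """Remove the spatial baseline signal from one consumer isotope value.

    Subtracts the baseline isotope value at the consumer's sampling station
    and adds back the study-wide mean baseline, so corrected values are
    comparable across stations; exactly invertible given the local baselines.
    """
    for name, v in (("value", value), ("local_baseline", local_baseline), ("mean_baseline", mean_baseline)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite")
    return value - local_baseline + mean_baseline


def trophic_level(
    d15n: float, d15n_base: float, lambda_base: float = 2.0, enrichment: float = 3.4
) -> float:
    """Trophic level from δ15N enrichment above a primary-consumer baseline."""
    if enrichment <= 0:
        raise ValueError("enrichment (per-step Δ15N) must be > 0")
    return lambda_base + (d15n - d15n_base) / enrichment


def infer_baseline_d15n(
    d15n, tl, lambda_base: float = 2.0, enrichment: float = 3.4
) -> float:
    """Least-squares baseline δ15N from paired (δ15N, trophic level) values.

    With TL = λ + (δ15N − b)/Δ, the residual sum of squares over groups is
    minimised at b = mean(δ15N − Δ·(TL − λ)); useful for recovering the
    baseline implied by a published trophic-level table.
    """
    d15n = np.asarray(d15n, dtype=float)
    tl = np.asarray(tl, dtype=float)
    if d15n.shape != tl.shape or d15n.size == 0:
        raise ValueError("d15n and tl must be equal-length, non-empty")
    if enrichment <= 0:
        raise ValueError("enrichment must be > 0")
    return float(np.mean(d15n - enrichment * (tl - lambda_base)))


def proportional_tef(d15n_consumer: float, intercept: float = 5.92, slope: float = 0.27) -> float:
    """Proportional nitrogen TEF: Δ15N = 5.92 − 0.27 · δ15N_consumer."""
    return intercept - slope * d15n_consumer


@dataclass
class StationBaselines:
    """Per-station baseline isotope values with the study-wide means."""

    table: pd.DataFrame  # index station_id, columns d13c, d15n
    mean_d13c: float
    mean_d15n: float
    filled_from: dict[str, str]  # stations whose baseline was borrowed, -> donor


def station_baselines(
    samples: pd.DataFrame,
    baseline_species: str,
    stations: pd.DataFrame | None = None,
) -> StationBaselines:
    """Mean baseline-species isotope values per station.

    Stations without any baseline sample borrow the nearest-by-depth station's
    baseline (requires a station table with depths); each fill is logged.
    """
    base = samples[samples["species"] == baseline_species]
    if base.empty:
        raise ValueError(f"baseline species {baseline_species!r} not present in samples")
    table = base.groupby("station_id")[["d13c", "d15n"]].mean()
    filled: dict[str, str] = {}
    if stations is not None:
        depths = stations.set_index("station_id")["depth"]
        missing = [s for s in samples["station_id"].unique() if s not in table.index]
        for st in missing:
            if st not in depths.index:
                raise ValueError(f"station {st!r} has no baseline samples and no depth record")
            have = [s for s in table.index if s in depths.index]
            donor = min(have, key=lambda s: abs(depths[s] - depths[st]))
            table.loc[st] = table.loc[donor]
            filled[st] = donor
            logger.warning("station %s lacks baseline samples; using nearest-depth station %s", st, donor)
    else:
        missing = set(samples["station_id"].unique()) - set(table.index)
        if missing:
            raise ValueError(
                f"stations without baseline samples (supply a station table to fill by depth): {sorted(missing)}"
            )
    return StationBaselines(
        table=table.sort_index(),
        mean_d13c=float(base["d13c"].mean()),
        mean_d15n=float(base["d15n"].mean()),
        filled_from=filled,
    )


def baseline_correct_frame(samples: pd.DataFrame, baselines: StationBaselines) -> pd.DataFrame:
    """Baseline-correct every sample's δ13C and δ15N, per station."""
    out = samples.copy()
    missing = sorted(set(out["station_id"]) - set(baselines.table.index))
    if missing:
        raise ValueError(f"no local baseline for station(s): {missing}")
    local = baselines.table.loc[out["station_id"]]
    out["d13c"] = out["d13c"].to_numpy() - local["d13c"].to_numpy() + baselines.mean_d13c
    out["d15n"] = out["d15n"].to_numpy() - local["d15n"].to_numpy() + baselines.mean_d15n
    return out


def lipid_correct_frame(samples: pd.DataFrame) -> pd.DataFrame:
    """Vectorised lipid correction; samples without C:N are left unchanged."""
    out = samples.copy()
    if "c_to_n" not in out.columns:
        return out
    cn = out["c_to_n"].to_numpy(dtype=float)
    if np.any(cn[np.isfinite(cn)] < 0):
        raise ValueError("C:N ratios must be >= 0")
    mask = np.isfinite(cn) & (cn > LIPID_CN_THRESHOLD)
    out.loc[mask, "d13c"] = out.loc[mask, "d13c"] - 3.32 + 0.99 * cn[mask]
    return out


def summarize_groups(
    samples: pd.DataFrame,
    d15n_base: float,
    tef: TefModel | None = None,
    group_map: dict[str, str] | None = None,
    lambda_base: float = 2.0,
    enrichment: float = 3.4,
) -> list[GroupSummary]:
    """Per-functional-group sample counts, isotope means ± SD, trophic level
    and nitrogen TEF summaries.

    SDs use the sample (n−1) convention; single-member groups report sd = 0
    and are flagged. Trophic levels use the fixed per-step enrichment of
    3.4 ‰ even when the mixing model later uses the proportional TEF — the
    two conventions serve different estimators. If ``group_map`` is given it
    overrides the samples' own functional_group column (species -> group).
    """
    tef = tef or TefModel()
    df = samples.copy()
    if group_map is not None:
        unmapped = sorted(set(df["species"]) - set(group_map))
        if unmapped:
            raise ValueError(f"species without group mapping: {unmapped}")
        df["functional_group"] = df["species"].map(group_map)
    if df["functional_group"].isna().any():
        raise ValueError("every sample must carry a functional group")

    summaries: list[GroupSummary] = []
    for group, sub in df.groupby("functional_group", sort=True):
        n = len(sub)
        if n == 0:  # groupby never yields these, kept for clarity
            logger.warning("group %s is empty; excluded from summaries", group)
            continue
        single = n == 1
        if single:
            logger.warning("group %s has a single member; SDs reported as 0", group)

        def _sd(x):
            return 0.0 if single else float(np.std(x, ddof=1))

        d13c = sub["d13c"].to_numpy(dtype=float)
        d15n = sub["d15n"].to_numpy(dtype=float)
        tls = lambda_base + (d15n - d15n_base) / enrichment
        tefs = np.array([tef.nitrogen_mean(v) for v in d15n])
        summaries.append(
            GroupSummary(
                group=str(group),
                n=n,
                d13c_mean=float(d13c.mean()),
                d13c_sd=_sd(d13c),
                d15n_mean=float(d15n.mean()),
                d15n_sd=_sd(d15n),
                tl_mean=float(tls.mean()),
                tl_sd=_sd(tls),
                tef_d15n_mean=float(tefs.mean()),
                tef_d15n_sd=_sd(tefs),
                single_member=single,
            )
        )
    return summaries


def summaries_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Table-shaped report: one row per functional group."""
    return pd.DataFrame(
        {
            "group": [s.group for s in summaries],
            "n": [s.n for s in summaries],
            "d13c_mean": [s.d13c_mean for s in summaries],
            "d13c_sd": [s.d13c_sd for s in summaries],
            "d15n_mean": [s.d15n_mean for s in summaries],
            "d15n_sd": [s.d15n_sd for s in summaries],
            "tl_mean": [s.tl_mean for s in summaries],
            "tl_sd": [s.tl_sd for s in summaries],
            "tef_d15n_mean": [s.tef_d15n_mean for s in summaries],
            "tef_d15n_sd": [s.tef_d15n_sd for s in summaries],
            "single_member": [s.single_member for s in summaries],
        }
    )
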