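"""Ingest, cleaning, trait scoring and end-to-end orchestration.

The long-format EMA CSV has columns ``person_id,timestamp,felt,expressed``
(ISO-8601 timestamps; responses 0-100 or empty).  Cleaning applies two
rules per person, in order: the first completed survey is dropped (the
expressed-love item refers to the previous survey, which does not exist at
the first prompt), then a forward scan drops any record arriving less than
one minute after the previously retained record.  Times are re-expressed in
hours from the first retained record.

``run_pipeline`` chains cleaning, the hierarchical fit, the group summary,
lag-curve/peak-lag derivation at the group-mean drift, person point
estimates, trait scoring and the trait-association grid, writing all
tables plus a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import ct_dynamics, evidence, inference
from .state_space import ObservationSeries

logger = logging.getLogger("lovedyn")

MIN_GAP_MINUTES = 1.0
MIN_RETAINED = inference.MIN_OCCASIONS


def _rule_indices(hours: np.ndarray, drop_first: bool = True) -> list[int]:
    """Indices kept by the two rules, applied in order on sorted times."""
    start = 1 if drop_first else 0
    if hours.size <= start:
        return []
    keep = [start]
    for i in range(start + 1, hours.size):
        if (hours[i] - hours[keep[-1]]) * 60.0 >= MIN_GAP_MINUTES:
            keep.append(i)
    return keep


def _prepare(raw: pd.DataFrame) -> pd.DataFrame:
    df = raw.copy()
    required = {"person_id", "timestamp", "felt", "expressed"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"EMA table missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def _retained_after_rules(raw: pd.DataFrame, drop_first: bool = True) -> dict:
    """Retained-record count per person (no occasion floor applied)."""
    df = _prepare(raw)
    out = {}
    for pid, grp in df.groupby("person_id", sort=True):
        grp = grp.sort_values("timestamp")
        hours = ((grp["timestamp"] - grp["timestamp"].iloc[0])
                 .dt.total_seconds() / 3600.0).to_numpy()
        out[pid] = len(_rule_indices(hours, drop_first=drop_first))
    return out


def clean_series(raw: pd.DataFrame) -> list[ObservationSeries]:
    """Apply the cleaning rules and return one series per retained person.

    Persons left with fewer than ``MIN_RETAINED`` records are excluded with
    a warning.  Removal counts are logged per rule.
    """
    df = _prepare(raw)
    out = []
    n_initial = n_close = 0
    for pid, grp in df.groupby("person_id", sort=True):
        grp = grp.sort_values("timestamp")
        hours = ((grp["timestamp"] - grp["timestamp"].iloc[0])
                 .dt.total_seconds() / 3600.0).to_numpy()
        keep = _rule_indices(hours)
        if hours.size:
            n_initial += 1
        n_close += max(hours.size - 1, 0) - len(keep)
        if len(keep) < MIN_RETAINED:
            logger.warning(
                "person %r excluded: %d retained record(s) (< %d)",
                pid, len(keep), MIN_RETAINED,
            )
            continue
        vals = grp[["felt", "expressed"]].to_numpy(dtype=float)[keep]
        t = hours[keep]
        out.append(ObservationSeries(person_id=pid, times=t - t[0],
                                     values=vals))
    logger.info("cleaning: dropped %d initial and %d <1-min records; "
                "%d persons retained", n_initial, n_close, len(out))
    return out


#: Reverse-keyed well-being items map x -> 7 - x on the 1-6 scale.
WELLBEING_REVERSE_DEFAULT = (True, False, True, False)


def score_traits(
    traits: pd.DataFrame,
    wellbeing_reverse=WELLBEING_REVERSE_DEFAULT,
) -> pd.DataFrame:
    """Score trait scales to the per-person summary columns.

    Happiness: mean of 4 items on 1-7.  Flourishing: sum of 8 items on 1-7
    (range 8-56).  Emotional well-being: mean of 4 items on 1-6 after
    reverse-keying flagged items (x -> 7 - x).  Columns already provided as
    summaries (``happiness``, ``flourishing``, ``well_being``) pass through
    unchanged; item columns are ``happiness_1..4``, ``flourishing_1..8``,
    ``well_being_1..4``.
    """
    df = traits.copy()

    def _items(prefix, n, lo, hi):
        cols = [f"{prefix}_{i}" for i in range(1, n + 1)]
        if not all(c in df.columns for c in cols):
            return None
        block = df[cols].astype(float)
        bad = (block < lo) | (block > hi)
        if bad.any().any():
            rows = sorted(df.index[bad.any(axis=1)].tolist())
            raise ValueError(
                f"{prefix} items outside [{lo}, {hi}] at rows {rows}")
        return block

    h = _items("happiness", 4, 1, 7)
    if h is not None:
        df["happiness"] = h.mean(axis=1)
    f = _items("flourishing", 8, 1, 7)
    if f is not None:
        df["flourishing"] = f.sum(axis=1)
    w = _items("well_being", 4, 1, 6)
    if w is not None:
        rev = np.asarray(wellbeing_reverse, dtype=bool)
        block = w.to_numpy()
        block[:, rev] = 7.0 - block[:, rev]
        df["well_being"] = block.mean(axis=1)
    for col in ("happiness", "flourishing", "well_being", "sex"):
        if col not in df.columns:
            raise ValueError(f"trait table lacks '{col}' (items or summary)")
    return df


def render_tables(
    summary: pd.DataFrame, evidence_grid: pd.DataFrame, digits: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Printed-table renderings of the group summary and association grid.

    The summary gains a formatted ``95% CI`` column; each association cell
    becomes ``r[bf10]`` with a trailing asterisk on r when BF10 > 10.
    """
    s = summary.copy()
    s["mean"] = s["mean"].astype(float).round(digits)
    s["95% CI"] = [
        f"[{lo:.{digits}f}, {hi:.{digits}f}]"
        for lo, hi in zip(summary["ci_lower"], summary["ci_upper"])
    ]
    s = s[["feature", "mean", "95% CI"]]
    if evidence_grid.empty:
        return s, evidence_grid.copy()
    cells = evidence_grid.map(lambda ce: ce.cell(digits))
    return s, cells


def run_pipeline(
    ema_csv,
    traits_csv,
    out_dir,
    config: inference.MCMCConfig | None = None,
    prior: inference.GroupPrior | None = None,
    lag_grid_hours: np.ndarray | None = None,
) -> dict:
    """Run cleaning -> fit -> summaries -> dynamics -> associations.

    Writes ``group_summary.csv``, ``lag_curves.csv``, ``person_estimates.csv``,
    ``associations.csv`` (rendered cells) and ``manifest.json`` under
    ``out_dir`` and returns the artifact paths plus diagnostics.  Any stage
    failure removes partial outputs and re-raises with the stage name.
    """
    config = config or inference.MCMCConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    stage = "ingest"
    t0 = time.time()
    try:
        raw = pd.read_csv(ema_csv)
        traits = pd.read_csv(traits_csv)

        stage = "clean"
        series = clean_series(raw)
        if len(series) < 2:
            raise ValueError("fewer than 2 persons retained after cleaning")

        stage = "fit"
        post = inference.fit_hierarchical(series, prior=prior, config=config)

        stage = "summarize"
        summary = inference.summarize_group(post)
        summary_tm = inference.summarize_group(post, mode="transformed_mean")

        stage = "dynamics"
        feat = post.group_feature_draws().reshape(-1, 4).mean(axis=0)
        a_hat = np.array([[feat[0], feat[2]],
                          [feat[3], feat[1]]])
        grid = (lag_grid_hours if lag_grid_hours is not None
                else np.linspace(0.1, 10.0, 100))
        curves = ct_dynamics.lag_curves(a_hat, grid)
        peaks = {
            which: ct_dynamics.peak_cross_lag(a_hat, which)
            for which in ("expressed_to_felt", "felt_to_expressed")
        }

        stage = "estimates"
        est = inference.person_point_estimates(post)

        stage = "associate"
        scored = score_traits(traits)
        grid_ev = evidence.associate(est.reset_index(), scored)

        stage = "write"
        summary.to_csv(out / "group_summary.csv", index=False)
        written.append(out / "group_summary.csv")
        summary_tm.to_csv(out / "group_summary_transformed_mean.csv",
                          index=False)
        written.append(out / "group_summary_transformed_mean.csv")
        curves.to_csv(out / "lag_curves.csv")
        written.append(out / "lag_curves.csv")
        est.to_csv(out / "person_estimates.csv")
        written.append(out / "person_estimates.csv")
        s_fmt, cells = render_tables(summary, grid_ev)
        cells.to_csv(out / "associations.csv")
        written.append(out / "associations.csv")
        s_fmt.to_csv(out / "group_summary_rendered.csv", index=False)
        written.append(out / "group_summary_rendered.csv")

        manifest = {
            "seed": config.seed,
            "chains": config.chains,
            "iterations": config.iterations,
            "warmup": config.warmup,
            "n_persons": post.n_persons,
            "converged": post.converged,
            "rhat": post.rhat,
            "ess": post.ess,
            "n_nonstationary_draws": post.n_nonstationary,
            "peak_lags": {k: (None if v is None else list(v))
                          for k, v in peaks.items()},
            "runtime_seconds": round(time.time() - t0, 2),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        written.append(out / "manifest.json")
    except Exception as exc:
        for path in written:
            Path(path).unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return {
        "out_dir": str(out),
        "manifest": manifest,
        "summary": summary,
        "associations": grid_ev,
        "posterior": post,
    }
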