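"""Per-line behavioural components of mate choice from factorial trial tables.

For each response channel the design yields a chooser-by-partner matrix of
cell means (one cell per line pairing).  From a chooser line's row of
cell means we compute:

* **responsiveness** — the unweighted mean of its cell means: overall
  motivation to mate, regardless of partner genotype;
* **choosiness** — the variability of its cell means across partner
  genotypes.  The primary measure is the sample SD among cell means;
  alternative measures from the preference literature (coefficient of
  variation, CV squared, and two "preference strength" contrasts of the
  maximum response against the mean) are provided for sensitivity
  analyses.

From a partner line's column we compute **global attractiveness** — the
unweighted mean of its cell means across chooser lines — together with
its inverse, so that for latency channels larger values mean more
attractive.

Channel roles follow fly courtship biology: copulation latency is
female-controlled (chooser = female line), while courtship latency and
copulation duration are male-controlled (chooser = male line).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "CHOOSER_ROLE",
    "CHOOSINESS_MEASURES",
    "cell_means",
    "responsiveness",
    "choosiness",
    "global_attractiveness",
    "line_components",
]

logger = logging.getLogger(__name__)

CHANNELS = ("courtship_latency", "copulation_latency", "copulation_duration")

#: Which sex's line is the chooser for each channel.
CHOOSER_ROLE = {
    "courtship_latency": "male_line",
    "copulation_latency": "female_line",
    "copulation_duration": "male_line",
}

CHOOSINESS_MEASURES = ("sd", "cv", "cv2", "strength_total_sd", "strength_max_sd")


def _roles(channel: str) -> tuple[str, str]:
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    chooser = CHOOSER_ROLE[channel]
    partner = "female_line" if chooser == "male_line" else "male_line"
    return chooser, partner


def _channel_values(trials: pd.DataFrame, channel: str,
                    mated_only: bool | None) -> pd.DataFrame:
    """Rows carrying a defined value for the channel, post filtering."""
    chooser, partner = _roles(channel)
    if channel == "copulation_duration":
        sub = trials[trials["mated"].astype(bool)]
    elif channel == "copulation_latency":
        if mated_only is None:
            mated_only = True
        sub = trials[trials["courted"].astype(bool)]
        if mated_only:
            sub = sub[sub["mated"].astype(bool)]
    else:  # courtship latency defined only when courtship occurred
        sub = trials[trials["courted"].astype(bool)]
    sub = sub.dropna(subset=[channel])
    return sub[[chooser, partner, channel]].rename(
        columns={chooser: "chooser_line", partner: "partner_line", channel: "value"})


def cell_means(trials: pd.DataFrame, channel: str,
               mated_only: bool | None = None,
               log_scale: bool = False) -> pd.DataFrame:
    """Per-(chooser line, partner line) n, mean and sample SD of a channel.

    Parameters
    ----------
    trials
        Long trial table (one row per no-choice trial).
    channel
        One of ``CHANNELS``.
    mated_only
        For copulation latency: if True (default), only mated trials
        enter the cell statistics; if False, censored trials enter at
        the censor time (their recorded latency).  Copulation duration
        is always restricted to mated pairs; courtship latency to pairs
        that courted.
    log_scale
        Compute statistics on natural-log seconds instead of seconds.

    Returns a DataFrame with columns chooser_line, partner_line,
    channel, n, mean, sd (sd is NaN for singleton cells).  Empty cells
    are omitted with a logged warning.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    vals = _channel_values(trials, channel, mated_only)
    if log_scale:
        vals = vals.assign(value=np.log(vals["value"]))
    grouped = vals.groupby(["chooser_line", "partner_line"], observed=True)["value"]
    out = grouped.agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    out.insert(2, "channel", channel)

    chooser, partner = _roles(channel)
    expected = {(c, p) for c in trials[chooser].unique() for p in trials[partner].unique()}
    got = set(zip(out["chooser_line"], out["partner_line"]))
    missing = expected - got
    if missing:
        logger.warning("%d empty cell(s) omitted for %s: %s",
                       len(missing), channel, sorted(missing)[:5])
    return out


def responsiveness(cells: pd.DataFrame) -> pd.Series:
    """Unweighted mean of cell means per chooser line (seconds)."""
    if len(cells) == 0:
        raise ValueError("no cells provided")
    return cells.groupby("chooser_line", observed=True)["mean"].mean().rename("responsiveness")


def _line_trial_sd(trials: pd.DataFrame, channel: str,
                   mated_only: bool | None, log_scale: bool = False) -> pd.Series:
    vals = _channel_values(trials, channel, mated_only)
    if log_scale:
        vals = vals.assign(value=np.log(vals["value"]))
    return vals.groupby("chooser_line", observed=True)["value"].std(ddof=1)


def choosiness(cells: pd.DataFrame, measure: str = "sd",
               trials: pd.DataFrame | None = None,
               channel: str | None = None,
               mated_only: bool | None = None,
               log_scale: bool = False) -> pd.Series:
    """Choosiness per chooser line, under the requested measure.

    ``sd``: sample SD among the line's cell means (the primary measure).
    ``cv``: SD / mean; ``cv2``: CV squared.
    ``strength_total_sd``: (max cell mean - grand mean of cell means) /
    SD of all the line's trial values; ``strength_max_sd``: same
    numerator / trial SD within the cell attaining the maximum mean.
    The strength measures need the trial table.
    """
    if measure not in CHOOSINESS_MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {CHOOSINESS_MEASURES}")
    counts = cells.groupby("chooser_line", observed=True)["mean"].size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"choosiness needs >= 2 cells per chooser line; offending lines: {bad}")

    g = cells.groupby("chooser_line", observed=True)["mean"]
    sd = g.std(ddof=1)
    if measure == "sd":
        return sd.rename("choosiness_sd")
    if measure in ("cv", "cv2"):
        mean = g.mean()
        if (mean == 0).any():
            raise ValueError("zero mean response: coefficient of variation undefined")
        cv = sd / mean
        return (cv if measure == "cv" else cv ** 2).rename(f"choosiness_{measure}")

    if trials is None or channel is None:
        raise ValueError(f"measure {measure!r} requires the trial table and channel")
    num = g.max() - g.mean()
    if measure == "strength_total_sd":
        denom = _line_trial_sd(trials, channel, mated_only, log_scale=log_scale)
    else:  # strength_max_sd: trial SD within the max-mean cell
        idx = cells.loc[cells.groupby("chooser_line", observed=True)["mean"].idxmax()]
        denom = idx.set_index("chooser_line")["sd"]
    denom = denom.reindex(num.index)
    if (denom == 0).any() or denom.isna().any():
        bad = denom.index[(denom == 0) | denom.isna()].tolist()
        raise ValueError(f"zero or undefined trial SD for lines {bad}: "
                         f"preference-strength measure undefined")
    return (num / denom).rename(f"choosiness_{measure}")


def global_attractiveness(cells: pd.DataFrame) -> pd.DataFrame:
    """Partner-line attractiveness: mean of cell means across chooser lines.

    Returns columns ``global_attractiveness`` (seconds; for latency
    channels lower = more attractive) and ``inverse_attractiveness``
    (1/seconds; higher = more attractive).
    """
    if len(cells) == 0:
        raise ValueError("no cells provided")
    mean = cells.groupby("partner_line", observed=True)["mean"].mean()
    if (mean == 0).any():
        raise ValueError("zero mean latency: inverse attractiveness undefined")
    return pd.DataFrame({
        "global_attractiveness": mean,
        "inverse_attractiveness": 1.0 / mean,
    })


def line_components(trials: pd.DataFrame, channel: str,
                    mated_only: bool | None = None,
                    log_scale: bool = False) -> pd.DataFrame:
    """All per-line components for one channel, one row per line.

    Chooser-role columns (responsiveness and every choosiness measure)
    and partner-role columns (global and inverse attractiveness) are
    joined on line id, so for shared-genotype designs each row carries
    both sexes' components of one genotype.
    """
    cells = cell_means(trials, channel, mated_only=mated_only, log_scale=log_scale)
    out = responsiveness(cells).to_frame()
    for measure in CHOOSINESS_MEASURES:
        out[f"choosiness_{measure}"] = choosiness(
            cells, measure, trials=trials, channel=channel,
            mated_only=mated_only, log_scale=log_scale)
    attr = global_attractiveness(cells)
    out = out.join(attr, how="outer")
    out.index.name = "line"
    out.insert(0, "channel", channel)
    return out.reset_index()
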