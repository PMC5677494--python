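"""Rendering of the analysis tables: effort ledger and parameter estimates.

Tables mirror the conventional monitoring-report layout: an effort ledger
with per-phase survey effort (footprint effort bracketed), observation totals
and encounter rates; and a parameter table with raw (link-scale) estimates
and 95% credible intervals alongside their response-level transforms and the
credible-interval significance rule.  Parameters are rounded to 3 decimals,
counts get thousands separators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import (
    PosteriorSamples,
    credible_interval,
    response_level,
    significance,
)

CONTRAST_LABELS = {
    "pre_vs_con": "Preconstruction versus construction",
    "con_vs_op": "Construction versus operation",
    "pre_vs_op": "Preconstruction versus operation",
}
SEASTATE_LABEL = "Good sea state versus poor sea state"


def parameter_rows_from_draws(post: PosteriorSamples) -> list[tuple]:
    """(label, draws, link) rows for the rendered parameter table."""
    rows = [(CONTRAST_LABELS[k], post.stacked(k), "log") for k in CONTRAST_LABELS]
    if post.family == "ZIP":
        rows.append((SEASTATE_LABEL, post.stacked("gamma_cond"), "logit"))
    return rows


def render_parameter_table(post: PosteriorSamples) -> pd.DataFrame:
    """Raw and response-level estimates with CrIs and the significance flag."""
    recs = []
    for label, draws, link in parameter_rows_from_draws(post):
        est = float(np.mean(draws))
        lo, hi = credible_interval(draws)
        recs.append(_parameter_record(label, est, lo, hi, link))
    return pd.DataFrame(recs)


def parameter_table_from_raw(rows) -> pd.DataFrame:
    """Build the same table from given raw (link-scale) estimates and CrIs.

    ``rows`` is an iterable of ``(label, estimate, lo, hi, link)``.  Response
    columns are the inverse-link transforms; significance follows the
    CrI-bounds-zero rule applied to the raw interval.
    """
    return pd.DataFrame([_parameter_record(*row) for row in rows])


def _parameter_record(label, est, lo, hi, link):
    r_est, r_lo, r_hi = response_level(est, lo, hi, link)
    sig = (lo > 0 and hi > 0) or (lo < 0 and hi < 0)
    return {
        "parameter": label,
        "raw_estimate": round(est, 3),
        "raw_lo": round(lo, 3),
        "raw_hi": round(hi, 3),
        "response_estimate": round(r_est, 3),
        "response_lo": round(r_lo, 3),
        "response_hi": round(r_hi, 3),
        "significant": "Yes" if sig else "No",
    }


def significance_from_draws(draws) -> str:
    return "Yes" if significance(draws) else "No"


def render_effort_table(ledger: pd.DataFrame) -> pd.DataFrame:
    """Format the effort ledger in the printed-table style."""
    out = []
    for _, r in ledger.iterrows():
        eff = f"{r['effort_km']:,.0f}"
        if np.isfinite(r.get("footprint_km", np.nan)):
            eff += f" ({r['footprint_km']:,.0f})"
        rate = f"{r['rate_per_km']:.2f}"
        rate += " (n/a)" if not np.isfinite(r["rate_se"]) else f" (±{r['rate_se']:.3f})"
        out.append(
            {
                "phase": r["phase"],
                "effort_km": eff,
                "observations": f"{int(r['observations']):,}",
                "rate_per_km": rate,
            }
        )
    return pd.DataFrame(out)


def format_table(df: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a table."""
    return df.to_string(index=False)
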