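"""Batch fitting across sections and group comparison of BMRF parameters.

A *manifest* is a CSV with one row per section: ``path`` (section CSV) and
``group`` (cohort label, e.g. young/geriatric).  The BMRF is fitted to each
section and the per-section (alpha, beta) estimates are compared between
two groups with a Welch t test and a Mann-Whitney U test — a pragmatic
post-hoc comparison; a joint hierarchical model across sections is out of
scope here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .bmrf import fit_bmrf
from .geometry import PruneConfig, delaunay_network
from .section_io import encode_binary, read_section_csv, register_result

__all__ = ["GroupComparison", "batch_fit", "compare_group_params"]

logger = logging.getLogger("myofibspat")


@register_result
@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    group_labels: tuple
    group_means: tuple
    t_p: float
    mw_p: float
    per_section_estimates: tuple  # rows of (section, group, alpha, beta)


def batch_fit(
    manifest: str | Path | pd.DataFrame,
    fast_labels: Iterable[str],
    prune: PruneConfig | None = None,
) -> pd.DataFrame:
    """Fit the BMRF to every section of a manifest.

    Returns a DataFrame with columns (section, group, n, alpha, beta).
    Per-section failures are logged and skipped rather than aborting the
    batch.
    """
    if isinstance(manifest, (str, Path)):
        manifest = pd.read_csv(manifest)
    if manifest.empty:
        raise ValueError("empty manifest: need at least one (path, group) row")
    for col in ("path", "group"):
        if col not in manifest.columns:
            raise ValueError(f"manifest is missing the {col!r} column")
    rows = []
    for rec in manifest.itertuples(index=False):
        try:
            section = read_section_csv(rec.path)
            labels = encode_binary(section, fast_labels)
            network = delaunay_network(section, prune=prune)
            fit = fit_bmrf(network, labels)
            rows.append({
                "section": str(rec.path), "group": str(rec.group),
                "n": section.n, "alpha": fit.alpha, "beta": fit.beta,
            })
        except Exception as exc:
            logger.error("section %s failed: %s", rec.path, exc)
    if not rows:
        raise ValueError("no section in the manifest could be processed")
    return pd.DataFrame(rows)


def compare_group_params(
    fit_table: pd.DataFrame,
    parameter: str = "beta",
    welch: bool = True,
) -> GroupComparison:
    """Two-sample comparison of per-section BMRF parameter estimates.

    Welch's t test by default (``welch=False`` pools variances) and a
    two-sided Mann-Whitney U test: exact enumeration for groups of at most
    20 sections without ties, normal approximation with tie correction
    otherwise.
    """
    if parameter not in ("alpha", "beta"):
        raise ValueError("parameter must be 'alpha' or 'beta'")
    groups = sorted(fit_table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    a = fit_table.loc[fit_table["group"] == groups[0], parameter].to_numpy(float)
    b = fit_table.loc[fit_table["group"] == groups[1], parameter].to_numpy(float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 sections")
    t_res = stats.ttest_ind(a, b, equal_var=not welch)
    small = max(len(a), len(b)) <= 20
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (small and no_ties) else "asymptotic"
    mw_res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    table = tuple(
        (str(r.section), str(r.group), float(r.alpha), float(r.beta))
        for r in fit_table.itertuples(index=False)
    )
    return GroupComparison(
        parameter=parameter,
        group_labels=(groups[0], groups[1]),
        group_means=(float(a.mean()), float(b.mean())),
        t_p=float(t_res.pvalue),
        mw_p=float(mw_res.pvalue),
        per_section_estimates=table,
    )
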