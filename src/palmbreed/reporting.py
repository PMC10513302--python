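"""Configuration parsing, summary tables and figures.

Endpoint comparisons across methods use paired t-tests over replicates
(methods share identical generation-0 populations within a replicate) with
Holm correction for the number of pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import fields

import numpy as np
import pandas as pd
import yaml

from .scheme import RunResult, SchemeConfig

logger = logging.getLogger(__name__)


def load_config(path) -> SchemeConfig:
    """Load a scenario configuration from a YAML file.

    Keys mirror :class:`SchemeConfig` fields; unknown keys are an error so
    typos fail fast.  A ``preset`` key ("desk" or "full") selects the base
    preset before overrides apply.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> SchemeConfig:
    raw = dict(raw)
    preset = raw.pop("preset", "desk")
    valid = {f.name for f in fields(SchemeConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    for key in ("gs_pt_cycles", "var_a_target"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    factory = SchemeConfig.full_scale if preset == "full" else SchemeConfig.desk
    cfg = factory(**raw)
    logger.info("configuration: %s", cfg)
    return cfg


def scenario_grid(
    schemes=("RRS", "RRGS"),
    candidate_counts=(120,),
    methods=("conventional",),
    c_delta_f=(0.25,),
) -> pd.DataFrame:
    """Expand a scenario grid: one row per unique (scheme, candidates, method).

    Mate-selection methods are expanded over the c_dF levels; all other
    methods ignore that axis.  Duplicate cells are an error.
    """
    rows = []
    for scheme in schemes:
        for n_cand in candidate_counts:
            for method in methods:
                levels = c_delta_f if method == "MS" else (None,)
                for c in levels:
                    m = f"MS_{int(round(c * 100))}" if method == "MS" else method
                    rows.append(
                        {"scheme": scheme, "n_candidates": n_cand, "method": m}
                    )
    grid = pd.DataFrame(rows)
    if grid.duplicated().any():
        raise ValueError("duplicate scenario cells in grid")
    return grid


GENERATION_COLUMNS = [
    "replicate", "scheme", "method", "generation", "years",
    "F_pedigree", "F_snp", "F_qtl_bn", "F_qtl_bw", "ffb_hybrid",
]


def summarize(result: RunResult) -> dict:
    """Summary tables from a scenario run.

    Returns ``generations`` (tidy per-generation), ``endpoints`` (mean +- SD
    of final inbreeding and progress per scheme x method) and
    ``pairwise_tests`` (Holm-corrected paired t-tests between methods; the
    p-value columns are NaN with fewer than two replicates).
    """
    if result.generations.empty:
        raise ValueError("no completed replicates to report")
    prog = result.progress_summary()
    endpoints = (
        prog.groupby(["scheme", "method"], sort=False)
        .agg(
            n_replicates=("replicate", "nunique"),
            progress_pct_mean=("progress_pct", "mean"),
            progress_pct_sd=("progress_pct", "std"),
            annual_progress_mean=("annual_progress_pct", "mean"),
            annual_progress_sd=("annual_progress_pct", "std"),
            final_F_snp_mean=("final_F_snp", "mean"),
            final_F_snp_sd=("final_F_snp", "std"),
            delta_F_snp_mean=("delta_F_snp", "mean"),
            delta_F_pedigree_mean=("delta_F_pedigree", "mean"),
        )
        .reset_index()
    )
    tests = pairwise_method_tests(prog)
    return {"generations": result.generations, "endpoints": endpoints, "pairwise_tests": tests}


def pairwise_method_tests(
    progress: pd.DataFrame, metrics=("final_F_snp", "progress_pct")
) -> pd.DataFrame:
    """Paired t-tests between methods within each scheme, Holm-corrected."""
    from scipy import stats

    rows = []
    for scheme, grp in progress.groupby("scheme", sort=False):
        methods = list(dict.fromkeys(grp["method"]))
        for metric in metrics:
            pvals, pairs = [], []
            for m1, m2 in itertools.combinations(methods, 2):
                a = grp[grp["method"] == m1].set_index("replicate")[metric]
                b = grp[grp["method"] == m2].set_index("replicate")[metric]
                common = a.index.intersection(b.index)
                if len(common) < 2:
                    pairs.append((m1, m2, len(common), np.nan, np.nan))
                    pvals.append(np.nan)
                    continue
                t, p = stats.ttest_rel(a.loc[common], b.loc[common])
                pairs.append(
                    (m1, m2, len(common), float(a.loc[common].mean() - b.loc[common].mean()), p)
                )
                pvals.append(p)
            adj = _holm(pvals)
            for (m1, m2, n, diff, p), pa in zip(pairs, adj):
                rows.append(
                    {
                        "scheme": scheme,
                        "metric": metric,
                        "method_1": m1,
                        "method_2": m2,
                        "n_pairs": n,
                        "mean_diff": diff,
                        "p_value": p,
                        "p_holm": pa,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "scheme", "metric", "method_1", "method_2",
            "n_pairs", "mean_diff", "p_value", "p_holm",
        ],
    )


def _holm(pvals) -> list[float]:
    ps = np.asarray(pvals, dtype=float)
    ok = np.isfinite(ps)
    out = np.full(ps.size, np.nan)
    if ok.sum():
        from statsmodels.stats.multitest import multipletests

        out[ok] = multipletests(ps[ok], method="holm")[1]
    return out.tolist()


def write_report(result: RunResult, out_dir) -> dict:
    """Write the summary tables as CSVs under ``out_dir``; returns the tables."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = summarize(result)
    for name, tab in tables.items():
        tab.to_csv(out / f"{name}.csv", index=False)
    return tables


# ---------------------------------------------------------------------------
# Figures (optional; basic summaries only)
# ---------------------------------------------------------------------------


def plot_inbreeding_trajectories(generations: pd.DataFrame, metric: str = "F_snp"):
    """Mean inbreeding per generation, one line per method, panel per scheme."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    schemes = list(dict.fromkeys(generations["scheme"]))
    fig, axes = plt.subplots(1, len(schemes), figsize=(5 * len(schemes), 4), squeeze=False)
    for ax, scheme in zip(axes[0], schemes):
        sub = generations[generations["scheme"] == scheme]
        for method, grp in sub.groupby("method", sort=False):
            m = grp.groupby("generation")[metric].mean()
            ax.plot(m.index, m.values, marker="o", label=method)
        ax.set_xlabel("generation")
        ax.set_ylabel(metric)
        ax.set_title(scheme)
        ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_endpoint_bars(endpoints: pd.DataFrame, column: str = "annual_progress_mean"):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    labels = endpoints["scheme"] + " / " + endpoints["method"]
    ax.bar(labels, endpoints[column])
    ax.set_ylabel(column)
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    return fig
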