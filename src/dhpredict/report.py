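"""Summary tables, dispersion comparisons and the pipeline driver.

Ships a reference table of per-trait heritabilities and DH-haploid
phenotypic/genotypic correlations estimated in a Zheng58 x Chang7-2 maize
DH population (35 traits, environments BJ2014 and SJZ2014), used by worked
examples and as the scale reference for simulator defaults.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_reference_correlations",
    "summarize_column",
    "coefficient_of_variation",
    "compare_population_dispersion",
    "run_pipeline",
]


def load_reference_correlations() -> pd.DataFrame:
    """Bundled per-trait (h2_D, h2_H, rP, rG) reference table.

    Columns: trait, tissue (EI/FI/WP), trait_class (agronomic/stalk), env
    (BJ2014/SJZ2014), h2_D, h2_H, rP, rG. Values are printed at 2-decimal
    precision.
    """
    ref = importlib.resources.files("dhpredict.data") / "dh_hap_reference_correlations.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)


def summarize_column(table: pd.DataFrame, column: str, env: str):
    """(min, max, median) of one column within one environment.

    Median is the exact order statistic (middle value for odd n, mean of
    the two middle values for even n).
    """
    if column not in table.columns:
        raise KeyError(f"unknown column {column!r}")
    sub = table.loc[table["env"] == env, column].dropna()
    if sub.empty:
        raise ValueError(f"no rows for env {env!r}")
    v = np.sort(sub.to_numpy(dtype=float))
    return float(v.min()), float(v.max()), float(np.median(v))


def coefficient_of_variation(values) -> float:
    """Sample standard deviation normalized by the mean."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need >= 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(v.std(ddof=1) / m)


def compare_population_dispersion(pheno: pd.DataFrame, trait_class=None, class_map=None):
    """Compare DH vs haploid dispersion (CV) trait by trait.

    Returns a dict with a per-trait CV table, the count of traits where the
    haploid CV strictly exceeds the DH CV, a paired t-test across traits on
    the CV differences, and per-trait two-sample t-tests of the population
    means. Traits present in only one population are skipped.
    """
    df = pheno.copy()
    if class_map is not None:
        df["trait_class"] = df["trait"].map(class_map)
        if trait_class is not None:
            df = df[df["trait_class"] == trait_class]
    rows = []
    skipped = []
    for trait, grp in df.groupby("trait"):
        pops = {p: g["value"].dropna() for p, g in grp.groupby("population")}
        if "DH" not in pops or "HAP" not in pops:
            skipped.append(trait)
            continue
        cv_d = coefficient_of_variation(pops["DH"])
        cv_h = coefficient_of_variation(pops["HAP"])
        tt = stats.ttest_ind(pops["DH"], pops["HAP"], equal_var=False)
        rows.append(
            {
                "trait": trait,
                "cv_DH": cv_d,
                "cv_HAP": cv_h,
                "hap_greater": cv_h > cv_d,
                "mean_diff_t": float(tt.statistic),
                "mean_diff_p": float(tt.pvalue),
            }
        )
    cv_table = pd.DataFrame(rows)
    if cv_table.empty:
        raise ValueError("no traits shared by both populations")
    d = cv_table["cv_HAP"] - cv_table["cv_DH"]
    if np.allclose(d, 0.0):
        paired_t, paired_p = 0.0, 1.0
    else:
        paired = stats.ttest_rel(cv_table["cv_HAP"], cv_table["cv_DH"])
        paired_t, paired_p = float(paired.statistic), float(paired.pvalue)
    return {
        "cv_table": cv_table,
        "n_hap_greater": int(cv_table["hap_greater"].sum()),
        "n_traits": len(cv_table),
        "paired_t": paired_t,
        "paired_p": paired_p,
        "skipped": skipped,
    }


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

DEFAULT_PIPELINE_CONFIG = {
    "simulate": {
        "n_lines": 100,
        "chrom_lengths_cM": [150.0] * 3,
        "markers_per_chrom": [60] * 3,
        "n_traits": 4,
        "n_envs": 1,
        "n_blocks": 2,
        "h2": [0.5, 0.4, 0.3, 0.3],
        "rG": 0.6,
    },
    "models": ["gblup", "factor"],
    "crossval": {"repeats": 3, "fraction": 0.5, "metric": "cor"},
    "chain": {"burn_in": 200, "n_iter": 800, "thin": 5},
}


def run_pipeline(config=None, out_dir="pipeline_out", seed: int = 0) -> Path:
    """Run simulate -> QC -> GRM -> CV2 model comparison -> selection report.

    ``config`` is a nested dict (or YAML path) following
    ``DEFAULT_PIPELINE_CONFIG``. All artifacts are written as delimited
    text under ``out_dir`` along with a JSON log of seeds and versions.
    """
    from . import __version__
    from .crossval import compare_models, make_cv2_single_env, single_env_cv2_accuracy
    from .markers import compute_grm, qc_filter
    from .selection_theory import SelectionParams, relative_efficiency
    from .simpop import (
        SimConfig,
        block_covariance,
        compound_labels,
        derive_haploid_population,
        simulate_biparental_dh,
        simulate_phenotypes,
    )

    if config is None:
        config = DEFAULT_PIPELINE_CONFIG
    elif isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    sim = dict(DEFAULT_PIPELINE_CONFIG["simulate"], **config.get("simulate", {}))
    models = config.get("models", DEFAULT_PIPELINE_CONFIG["models"])
    known_models = {"gblup", "factor"}
    unknown = set(models) - known_models
    if unknown:
        raise ValueError(f"unknown model name(s): {sorted(unknown)}")
    cv_cfg = dict(DEFAULT_PIPELINE_CONFIG["crossval"], **config.get("crossval", {}))
    chain = dict(DEFAULT_PIPELINE_CONFIG["chain"], **config.get("chain", {}))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    n_traits = sim["n_traits"]
    h2 = np.asarray(sim["h2"], dtype=float)
    if h2.size != n_traits:
        raise ValueError("h2 must have one value per trait")
    rG = sim["rG"]
    R = np.full((n_traits, n_traits), rG) + (1 - rG) * np.eye(n_traits)
    G0, R0 = block_covariance(h2, R)
    cfg = SimConfig(
        n_lines=sim["n_lines"],
        chrom_lengths_cM=sim["chrom_lengths_cM"],
        markers_per_chrom=sim["markers_per_chrom"],
        n_traits=n_traits,
        n_envs=sim["n_envs"],
        n_blocks=sim["n_blocks"],
        G0=np.kron(np.eye(sim["n_envs"]), G0) if sim["n_envs"] > 1 else G0,
        R0=np.kron(np.eye(sim["n_envs"]), R0) if sim["n_envs"] > 1 else R0,
        seed=seed,
    )
    geno, origin = simulate_biparental_dh(cfg)
    hap = derive_haploid_population(geno)
    geno_qc, qc_report = qc_filter(geno)
    grm = compute_grm(geno_qc)
    labels = compound_labels(n_traits, sim["n_envs"])
    pheno = simulate_phenotypes(grm, cfg, labels=labels, seed=seed)

    geno.to_tsv(out / "genotypes.tsv")
    cfg.marker_map().to_csv(out / "marker_map.tsv", sep="\t", index=False)
    grm.to_tsv(out / "grm.tsv")
    pheno.to_csv(out / "phenotypes.csv", index=False)
    (out / "qc_report.txt").write_text(str(qc_report) + "\n")

    # line means for env 1, CV2 comparison: first trait focal, rest secondary
    env = labels["env"].iloc[0]
    sub = pheno[pheno["env"] == env]
    Y = sub.pivot_table(index="line_id", columns="trait", values="value").loc[grm.line_ids]
    traits = list(Y.columns)
    focal, secondary = traits[:1], traits[1:]
    plan = make_cv2_single_env(
        grm.line_ids, focal, secondary, J=cv_cfg["repeats"], fraction=cv_cfg["fraction"], seed=seed
    )
    metric = "genetic" if cv_cfg.get("metric") == "genetic" else "cor"
    acc = single_env_cv2_accuracy(
        Y, grm, plan, models=tuple(models), metric=metric, env=env, chain=chain, seed=seed
    )
    acc.to_csv(out / "accuracy_table.csv", index=False)
    if len(models) >= 2:
        n_test = int(len(grm.line_ids) * cv_cfg["fraction"] + 0.5)
        tests = compare_models(acc, models[1], models[0], len(grm.line_ids) - n_test, n_test)
        tests.to_csv(out / "model_comparison.csv", index=False)

    # selection-response verdicts from the generating heritabilities
    sel_rows = []
    for j, t in enumerate(traits):
        p = SelectionParams(
            h_H=float(np.sqrt(h2[j])), h_D=float(np.sqrt(h2[j])), sigma_A_D=1.0, r_A=rG
        )
        re, verdict = relative_efficiency(p)
        sel_rows.append({"trait": t, "relative_efficiency": re, "verdict": verdict})
    pd.DataFrame(sel_rows).to_csv(out / "selection_report.csv", index=False)

    log = {
        "seed": seed,
        "version": __version__,
        "numpy": np.__version__,
        "n_lines": cfg.n_lines,
        "n_markers_post_qc": len(geno_qc.marker_ids),
        "models": list(models),
        "repeats": cv_cfg["repeats"],
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return out
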