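"""Orchestration of the tree-quintet experiment and its comparison statistics.

The experiment asks: if the same communities and the same traits are scored
on a purpose-built chronogram and on synthesis-style degraded variants of it,
how well do the resulting diversity values and signal estimates agree?

Agreement is summarised three ways, per metric and per variant:

* per-replicate Spearman rank correlations (median and mean over replicates)
  between values on the purpose tree and on the variant — rank-based because
  relative, not absolute, diversity is what community comparisons use;
* scaled through-origin mixed-model slopes: both value vectors are
  standardized globally, the purpose values regressed on the variant values
  with no fixed intercept and a random intercept per replicate dataset
  (beta designs add site1-within-replicate and site2-within-site1 variance
  components); a slope below 1 means the variant runs high relative to the
  purpose tree;
* signal summaries: mean |lambda difference| (lambda estimates on the purpose
  tree have near-zero variance, so correlations are uninformative) and the
  Spearman correlation of K estimates, plus tip-reshuffling type-I-error
  rates for both statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import spearmanr, wilcoxon

from .alpha import alpha_table
from .beta import beta_table
from .communities import simulate_communities
from .simulate import DegradationConfig, TreeSet, make_tree_set
from .traits import KEstimator, LambdaEstimator, simulate_traits_many
from .tree import write_newick

__all__ = [
    "ExperimentConfig",
    "ComparisonResult",
    "spearman_by_replicate",
    "lmm_slope_alpha",
    "lmm_slope_beta",
    "signal_comparison",
    "type1_error",
    "run_alpha_experiment",
    "run_beta_experiment",
    "run_signal_experiment",
    "run_type1_experiment",
    "run_experiment",
    "correlation_summary",
    "slope_summary_alpha",
    "slope_summary_beta",
    "signal_summary",
    "ALPHA_METRICS",
    "BETA_METRICS",
    "VARIANTS",
]

ALPHA_METRICS = ("PD", "MPD", "MNTD")
BETA_METRICS = ("Unif", "MPD_beta", "MNTD_beta", "PCD")
VARIANTS = ("apg", "zanne", "otl", "random")


def _rng(master: int, *path: int) -> np.random.Generator:
    """Named substream of the master seed (counter-based, documented order)."""
    return np.random.default_rng(np.random.SeedSequence([int(master), *map(int, path)]))


def _subseed(master: int, *path: int) -> int:
    return int(_rng(master, *path).integers(2**31))


# ----------------------------------------------------------------- statistics
def spearman_by_replicate(values_a, values_b) -> float:
    """Spearman rank correlation (average ranks for ties); NaN when either
    vector has zero variance."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(spearmanr(a, b).statistic)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def lmm_slope_alpha(purpose_values, synth_values, replicate_ids):
    """Through-origin mixed-model slope with a random intercept per replicate.

    Both vectors are globally standardized first.  Returns
    ``(slope, ci_low, ci_high)`` from a REML fit with a Wald 95% interval.
    """
    y = _standardize(np.asarray(purpose_values, dtype=float))
    x = _standardize(np.asarray(synth_values, dtype=float))
    groups = np.asarray(replicate_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, x[:, None], groups=groups)
        try:
            fit = model.fit(reml=True)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"mixed model failed to converge: {exc}") from exc
    slope = float(fit.fe_params[0])
    se = float(fit.bse_fe[0])
    if not np.isfinite(se):  # degenerate fit (zero residual variance)
        se = 0.0
    return slope, slope - 1.96 * se, slope + 1.96 * se


def lmm_slope_beta(purpose_values, synth_values, replicate_ids, site1_ids, site2_ids):
    """Beta-diversity analogue with nested random terms: replicate, site1
    within replicate, and site2 within site1.  Falls back to the single
    random-intercept design with a warning if the nested fit fails."""
    df = pd.DataFrame(
        {
            "y": _standardize(np.asarray(purpose_values, dtype=float)),
            "x": _standardize(np.asarray(synth_values, dtype=float)),
            "rep": np.asarray(replicate_ids).astype(str),
            "site1": np.asarray(site1_ids).astype(str),
        }
    )
    df["pair"] = df["site1"] + ":" + np.asarray(site2_ids).astype(str)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM.from_formula(
                "y ~ 0 + x",
                data=df,
                groups="rep",
                re_formula="1",
                vc_formula={"site1": "0 + C(site1)", "pair": "0 + C(pair)"},
            )
            fit = model.fit(reml=True)
        slope = float(fit.fe_params.iloc[0])
        se = float(fit.bse_fe.iloc[0])
        if not np.isfinite(se):
            se = 0.0
        return slope, slope - 1.96 * se, slope + 1.96 * se
    except (np.linalg.LinAlgError, ValueError) as exc:
        warnings.warn(f"nested beta mixed model failed ({exc}); "
                      "falling back to a single random intercept")
        return lmm_slope_alpha(purpose_values, synth_values, replicate_ids)


def signal_comparison(estimates_purpose, estimates_synth, statistic: str) -> dict:
    """Summary of paired signal estimates on purpose vs synthesis tree."""
    a = np.asarray(estimates_purpose, dtype=float)
    b = np.asarray(estimates_synth, dtype=float)
    if a.size != b.size:
        raise ValueError("paired estimate vectors must have equal length")
    if statistic == "lambda":
        return {
            "mean_abs_diff": float(np.abs(a - b).mean()),
            "mean_purpose": float(a.mean()),
            "mean_synth": float(b.mean()),
        }
    if statistic == "K":
        rho = spearman_by_replicate(a, b) if a.size >= 3 else np.nan
        if np.allclose(a, b):
            wp = 1.0
        else:
            wp = float(wilcoxon(a, b).pvalue)
        return {
            "spearman_rho": rho,
            "wilcoxon_p": wp,
            "mean_purpose": float(a.mean()),
            "mean_synth": float(b.mean()),
        }
    raise ValueError(f"unknown statistic {statistic!r}")


def type1_error(p_values, alpha: float = 0.05) -> dict:
    """Observed false-positive rate with a binomial normal-approximation CI."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    rate = float((p < alpha).mean())
    half = 1.96 * np.sqrt(max(rate * (1 - rate), 1e-12) / n)
    return {
        "rate": rate,
        "ci_low": max(0.0, rate - half),
        "ci_high": min(1.0, rate + half),
        "n": int(n),
    }


# -------------------------------------------------------------- configuration
@dataclass
class ExperimentConfig:
    """Scaled-down default study conditions (the full-scale design of 1,000
    replicates is a preset via ``paper_scale``)."""

    n_tips: int = 300
    root_age: float = 100.0
    degradation: DegradationConfig = field(default_factory=DegradationConfig)
    n_replicates: int = 100
    n_beta_replicates: int = 50
    n_sites: int = 30
    richness: int = 50
    sigma2_grid: tuple = (0.2, 0.75, 1.5)
    alpha_grid: tuple = (0.0, 0.05, 0.5, 1.0)
    n_signal_replicates: int = 100
    n_perm: int = 199
    n_rand_pcd: int = 199
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_tips",
            "n_replicates",
            "n_beta_replicates",
            "n_sites",
            "richness",
            "n_signal_replicates",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.sigma2_grid or not len(self.alpha_grid):
            raise ValueError("parameter grids must be nonempty")
        if isinstance(self.degradation, dict):
            self.degradation = DegradationConfig(**self.degradation)

    @classmethod
    def paper_scale(cls, **overrides) -> "ExperimentConfig":
        base = dict(
            n_replicates=1000,
            n_beta_replicates=1000,
            n_signal_replicates=1000,
            n_perm=999,
            n_rand_pcd=999,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "degradation" in data and isinstance(data["degradation"], dict):
            from .simulate import VariantSpec

            d = data["degradation"]
            kwargs = {}
            for v in ("apg", "zanne", "otl"):
                if v in d:
                    kwargs[v] = VariantSpec(**d[v])
            if "tip_drop_fraction" in d:
                kwargs["tip_drop_fraction"] = d["tip_drop_fraction"]
            data["degradation"] = DegradationConfig(**kwargs)
        for key in ("sigma2_grid", "alpha_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class ComparisonResult:
    correlations: pd.DataFrame  # kind, metric, tree, median_rho, mean_rho
    slopes_alpha: pd.DataFrame
    slopes_beta: pd.DataFrame
    signal: pd.DataFrame
    type1: pd.DataFrame
    manifest: dict


# ------------------------------------------------------------ experiment runs
def run_alpha_experiment(
    ts: TreeSet, n_replicates: int, n_sites: int, richness: int, seed: int
) -> pd.DataFrame:
    """Alpha diversity of every site on every tree, long format:
    columns replicate, site, tree, PD, MPD, MNTD."""
    pool = list(ts.common_tips)
    frames = []
    for rep in range(n_replicates):
        mat = simulate_communities(
            pool, n_sites=n_sites, richness=richness, seed=_rng(seed, 1, rep)
        )
        for name, tree in ts.trees.items():
            tab = alpha_table(mat, tree).reset_index(names="site")
            tab.insert(0, "tree", name)
            tab.insert(0, "replicate", rep)
            frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def run_beta_experiment(
    ts: TreeSet,
    n_replicates: int,
    n_sites: int,
    richness: int,
    n_rand_pcd: int,
    seed: int,
) -> pd.DataFrame:
    """Beta diversity of every unordered site pair on every tree (long).

    Community matrices are the same seed-substream as the alpha run, so the
    first ``n_replicates`` matrices coincide with the alpha experiment's.
    """
    pool = list(ts.common_tips)
    frames = []
    for rep in range(n_replicates):
        mat = simulate_communities(
            pool, n_sites=n_sites, richness=richness, seed=_rng(seed, 1, rep)
        )
        # one shared PCD seed per replicate: the random-assemblage draws are
        # then the same label sets on every tree, so identical trees give
        # identical PCD values
        pcd_seed = _subseed(seed, 4, rep)
        for name, tree in ts.trees.items():
            tab = beta_table(mat, tree, n_rand=n_rand_pcd, seed=pcd_seed)
            tab.insert(0, "tree", name)
            tab.insert(0, "replicate", rep)
            frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def correlation_summary(values: pd.DataFrame, metrics, by: str = "site") -> pd.DataFrame:
    """Median and mean per-replicate Spearman rho of each variant vs the
    purpose tree, per metric."""
    key = ["replicate", by] if by == "site" else ["replicate", "site1", "site2"]
    wide = values.pivot_table(index=key, columns="tree", values=list(metrics))
    rows = []
    for metric in metrics:
        for tree in VARIANTS:
            rhos = (
                wide[metric]
                .groupby(level="replicate")
                .apply(
                    lambda g: spearman_by_replicate(
                        g["purpose"].to_numpy(), g[tree].to_numpy()
                    )
                )
            )
            rows.append(
                {
                    "metric": metric,
                    "tree": tree,
                    "median_rho": float(np.nanmedian(rhos)),
                    "mean_rho": float(np.nanmean(rhos)),
                    "n_replicates": int(rhos.size),
                }
            )
    return pd.DataFrame(rows)


def slope_summary_alpha(values: pd.DataFrame, metrics=ALPHA_METRICS) -> pd.DataFrame:
    wide = values.pivot_table(
        index=["replicate", "site"], columns="tree", values=list(metrics)
    ).reset_index()
    rows = []
    for metric in metrics:
        for tree in VARIANTS:
            slope, lo, hi = lmm_slope_alpha(
                wide[(metric, "purpose")], wide[(metric, tree)], wide["replicate"]
            )
            rows.append(
                {"metric": metric, "tree": tree, "slope": slope, "ci_low": lo, "ci_high": hi}
            )
    return pd.DataFrame(rows)


def slope_summary_beta(values: pd.DataFrame, metrics=BETA_METRICS) -> pd.DataFrame:
    wide = values.pivot_table(
        index=["replicate", "site1", "site2"], columns="tree", values=list(metrics)
    ).reset_index()
    rows = []
    for metric in metrics:
        for tree in VARIANTS:
            slope, lo, hi = lmm_slope_beta(
                wide[(metric, "purpose")],
                wide[(metric, tree)],
                wide["replicate"],
                wide["site1"],
                wide["site2"],
            )
            rows.append(
                {"metric": metric, "tree": tree, "slope": slope, "ci_low": lo, "ci_high": hi}
            )
    return pd.DataFrame(rows)


def run_signal_experiment(
    ts: TreeSet,
    sigma2_grid,
    alpha_grid,
    n_replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate traits on the purpose tree and estimate lambda and K on all
    five trees.  Long format: sigma2, alpha, replicate, tree, lambda, K."""
    lam = {name: LambdaEstimator(tree) for name, tree in ts.trees.items()}
    kest = {name: KEstimator(tree) for name, tree in ts.trees.items()}
    frames = []
    for i, s2 in enumerate(sigma2_grid):
        for j, a in enumerate(alpha_grid):
            X = simulate_traits_many(
                ts.tree_purpose, s2, n_replicates, seed=_rng(seed, 2, i, j), alpha=a
            )
            for name in ts.trees:
                lam_df = lam[name].estimate_many(X)
                k_ser = kest[name].estimate_many(X)
                frames.append(
                    pd.DataFrame(
                        {
                            "sigma2": s2,
                            "alpha": a,
                            "replicate": np.arange(n_replicates),
                            "tree": name,
                            "lambda": lam_df["lambda"].to_numpy(),
                            "lambda_p": lam_df["p"].to_numpy(),
                            "K": k_ser.to_numpy(),
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


def signal_summary(signal: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (s2, a), grp in signal.groupby(["sigma2", "alpha"]):
        wide_l = grp.pivot(index="replicate", columns="tree", values="lambda")
        wide_k = grp.pivot(index="replicate", columns="tree", values="K")
        for tree in VARIANTS:
            lam_sum = signal_comparison(wide_l["purpose"], wide_l[tree], "lambda")
            k_sum = signal_comparison(wide_k["purpose"], wide_k[tree], "K")
            rows.append(
                {
                    "sigma2": s2,
                    "alpha": a,
                    "tree": tree,
                    "lambda_mean_abs_diff": lam_sum["mean_abs_diff"],
                    "lambda_mean_purpose": lam_sum["mean_purpose"],
                    "lambda_mean_synth": lam_sum["mean_synth"],
                    "K_spearman_rho": k_sum["spearman_rho"],
                    "K_wilcoxon_p": k_sum["wilcoxon_p"],
                    "K_mean_purpose": k_sum["mean_purpose"],
                    "K_mean_synth": k_sum["mean_synth"],
                }
            )
    return pd.DataFrame(rows)


def run_type1_experiment(
    ts: TreeSet, sigma2: float, n_replicates: int, n_perm: int, seed: int
) -> pd.DataFrame:
    """Type-I error of the lambda LRT and the K permutation test on traits
    whose values were reshuffled across tips (a true null)."""
    X = simulate_traits_many(ts.tree_purpose, sigma2, n_replicates, seed=_rng(seed, 3, 0))
    rng = _rng(seed, 3, 1)
    Xs = X.copy()
    for col in Xs.columns:
        Xs[col] = rng.permutation(Xs[col].to_numpy())
    rows = []
    for name, tree in ts.trees.items():
        lam = LambdaEstimator(tree)
        kest = KEstimator(tree)
        lam_p = lam.estimate_many(Xs)["p"].to_numpy()
        k_p = np.array(
            [
                kest.estimate(
                    Xs[c].reindex(kest.labels).to_numpy(),
                    n_perm=n_perm,
                    seed=_rng(seed, 3, 2, i),
                ).p_value
                for i, c in enumerate(Xs.columns)
            ]
        )
        for stat, pvals in (("lambda", lam_p), ("K", k_p)):
            res = type1_error(pvals)
            res.update({"tree": name, "statistic": stat})
            rows.append(res)
    return pd.DataFrame(rows)[["tree", "statistic", "rate", "ci_low", "ci_high", "n"]]


# -------------------------------------------------------------- orchestration
def run_experiment(config: ExperimentConfig, outdir=None) -> ComparisonResult:
    """Run the full comparison and optionally write all result tables.

    Reproducible from the master seed: trees, community matrices, traits,
    null draws and permutations each use a named substream.
    """
    ts = make_tree_set(
        config.n_tips, config.root_age, config.degradation, seed=_subseed(config.seed, 0)
    )
    alpha_vals = run_alpha_experiment(
        ts, config.n_replicates, config.n_sites, config.richness, config.seed
    )
    beta_vals = run_beta_experiment(
        ts,
        config.n_beta_replicates,
        config.n_sites,
        config.richness,
        config.n_rand_pcd,
        config.seed,
    )
    signal_vals = run_signal_experiment(
        ts, config.sigma2_grid, config.alpha_grid, config.n_signal_replicates, config.seed
    )
    corr_alpha = correlation_summary(alpha_vals, ALPHA_METRICS, by="site")
    corr_alpha.insert(0, "kind", "alpha")
    corr_beta = correlation_summary(beta_vals, BETA_METRICS, by="pair")
    corr_beta.insert(0, "kind", "beta")
    correlations = pd.concat([corr_alpha, corr_beta], ignore_index=True)
    slopes_alpha = slope_summary_alpha(alpha_vals)
    slopes_beta = slope_summary_beta(beta_vals)
    signal = signal_summary(signal_vals)
    type1 = run_type1_experiment(
        ts, config.sigma2_grid[0], config.n_signal_replicates, config.n_perm, config.seed
    )
    manifest = {
        "config": _config_dict(config),
        "n_common_tips": len(ts.common_tips),
        "root_ages": {name: tree.root_age() for name, tree in ts.trees.items()},
        "polytomies": {name: tree.polytomy_count() for name, tree in ts.trees.items()},
    }
    result = ComparisonResult(
        correlations, slopes_alpha, slopes_beta, signal, type1, manifest
    )
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "trees").mkdir(parents=True, exist_ok=True)
        for name, tree in ts.trees.items():
            (outdir / "trees" / f"tree_{name}.nwk").write_text(write_newick(tree) + "\n")
        alpha_vals.to_csv(outdir / "alpha.csv", index=False)
        beta_vals.to_csv(outdir / "beta.csv", index=False)
        signal_vals.to_csv(outdir / "signal.csv", index=False)
        correlations.to_csv(outdir / "correlations.csv", index=False)
        slopes_alpha.to_csv(outdir / "slopes_alpha.csv", index=False)
        slopes_beta.to_csv(outdir / "slopes_beta.csv", index=False)
        type1.to_csv(outdir / "type1.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return result


def _config_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    d["sigma2_grid"] = list(config.sigma2_grid)
    d["alpha_grid"] = list(config.alpha_grid)
    return d
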