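"""Monte-Carlo studies of MDMR level accuracy and power.

Generators draw N x P outcome matrices from four families (iid normal, a
symmetric bimodal mixture, log-normal, and equicorrelated multivariate
normal), all standardized to unit variance, optionally with a group mean
shift (dichotomous regressor) or an induced correlation with a continuous
regressor.  Experiment drivers wrap the generators to estimate empirical
type-I error at a grid of nominal levels, power as a function of effect
size, sample size, and regressor correlation, the familywise power of a
Bonferroni-corrected per-variable t-test comparator, and the agreement
between permutation and analytic F p-values.

Every driver is exactly reproducible from its seed; rejection rates are
reported with binomial standard errors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from . import core
from .distance import DataMatrix, GowerMatrix
from .core import DesignMatrix

__all__ = [
    "GeneratorSpec",
    "ExperimentReport",
    "generate_dataset",
    "level_accuracy_experiment",
    "power_experiment",
    "bonferroni_t_comparator",
    "power_vs_n_experiment",
    "continuous_power_experiment",
    "pvalue_agreement_study",
]

_FAMILIES = ("normal", "bimodal", "lognormal", "mvn_equicorr")

# defaults mirror the simulation settings exercised throughout: P=10 null
# studies, P=100 power studies, nominal levels 1..75%
DEFAULT_LEVELS = (1.0, 5.0, 10.0, 25.0, 50.0, 75.0)
DEFAULT_LEVEL_NS = (100, 50, 20, 10, 4)
DEFAULT_SHIFT_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.02), 10))
DEFAULT_FRACTIONS = (1.0, 0.5, 0.25, 0.10, 0.05)


@dataclass
class GeneratorSpec:
    """Settings for one synthetic dataset draw.

    shift is the per-group mean offset in SD units, applied to the first
    ceil(shifted_fraction * p) variables of the experimental group only;
    correlation is the equicorrelation parameter of the mvn_equicorr family;
    regressor_corr is the target correlation between a continuous regressor
    and each affected variable.
    """

    family: str = "normal"
    n: int = 100
    p: int = 10
    shift: float = 0.0
    shifted_fraction: float = 1.0
    correlation: float = 0.0
    regressor_type: str = "dichotomous"
    regressor_corr: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.regressor_type not in ("dichotomous", "continuous"):
            raise ValueError(f"unknown regressor_type {self.regressor_type!r}")
        if not 0 <= self.shifted_fraction <= 1:
            raise ValueError("shifted_fraction must be in [0, 1]")
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must be in [0, 1)")
        if not -1 < self.regressor_corr < 1:
            raise ValueError("regressor_corr must be in (-1, 1)")


def _standardized_noise(rng: np.random.Generator, family: str, n: int, p: int,
                        correlation: float) -> np.ndarray:
    """n x p draw with zero mean and unit variance from the chosen family."""
    if family == "normal":
        return rng.standard_normal((n, p))
    if family == "bimodal":
        # equal mixture of N(-1, 0.5^2) and N(+1, 0.5^2): variance 1.25
        signs = rng.integers(0, 2, size=(n, p)) * 2.0 - 1.0
        return (signs + 0.5 * rng.standard_normal((n, p))) / math.sqrt(1.25)
    if family == "lognormal":
        raw = np.exp(rng.standard_normal((n, p)))
        mean = math.exp(0.5)
        sd = math.sqrt((math.e - 1.0) * math.e)
        return (raw - mean) / sd
    # mvn_equicorr: compound-symmetric covariance (1-rho) I + rho J
    rho = correlation
    shared = rng.standard_normal((n, 1))
    return math.sqrt(1.0 - rho) * rng.standard_normal((n, p)) + math.sqrt(rho) * shared


def _draw(rng: np.random.Generator, spec: GeneratorSpec) -> tuple[np.ndarray, np.ndarray]:
    """Raw (values, regressor) arrays for one dataset."""
    n, p = spec.n, spec.p
    values = _standardized_noise(rng, spec.family, n, p, spec.correlation)
    n_affected = math.ceil(spec.shifted_fraction * p) if spec.shift or spec.regressor_corr else 0
    if spec.regressor_type == "dichotomous":
        x = np.zeros(n)
        x[n // 2:] = 1.0
        if spec.shift and n_affected:
            values[n // 2:, :n_affected] += spec.shift
    else:
        x = rng.standard_normal(n)
        r = spec.regressor_corr
        if r and n_affected:
            values[:, :n_affected] = (
                r * x[:, None] + math.sqrt(1.0 - r * r) * values[:, :n_affected]
            )
    return values, x


def generate_dataset(spec: GeneratorSpec,
                     rng: np.random.Generator | None = None
                     ) -> tuple[DataMatrix, DesignMatrix]:
    """One synthetic dataset: outcome matrix plus single-regressor design."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    values, x = _draw(rng, spec)
    data = DataMatrix(values,
                      [f"s{i + 1}" for i in range(spec.n)],
                      [f"v{j + 1}" for j in range(spec.p)])
    design = DesignMatrix(x, ["group" if spec.regressor_type == "dichotomous"
                              else "regressor"])
    return data, design


@dataclass
class ExperimentReport:
    """Long-format rejection-rate table with its full provenance."""

    table: pd.DataFrame
    config: dict
    seed: int
    thresholds: dict = field(default_factory=dict)

    def pivot(self, index: str, columns: str, values: str = "rate") -> pd.DataFrame:
        return self.table.pivot_table(index=index, columns=columns, values=values)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_json(self, path) -> None:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "thresholds": self.thresholds,
            "rows": self.table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _binom_se(rate: float, n: int) -> float:
    return math.sqrt(max(rate * (1.0 - rate), 0.0) / n)


def _fast_gower(values: np.ndarray) -> GowerMatrix:
    d = squareform(pdist(values))
    a = -0.5 * d * d
    row = a.mean(axis=1, keepdims=True)
    g = a - row - row.T + a.mean()
    return GowerMatrix(0.5 * (g + g.T))


def _sim_pvalue_pairs(spec: GeneratorSpec, n_sims: int, n_perm: int, seed: int,
                      want_perm: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Per-simulation (permutation p, analytic p) pairs under the spec.

    The analytic p-value uses the df-scaled statistic with df = (P, P*N - 2).
    """
    rng = np.random.default_rng(seed)
    p_perm = np.full(n_sims, np.nan)
    p_an = np.empty(n_sims)
    design_ids = ["x"]
    for s in range(n_sims):
        values, x = _draw(rng, spec)
        g = _fast_gower(values)
        design = DesignMatrix(x, design_ids)
        if want_perm:
            pp, f_obs, _ = core.permutation_test(
                g, design, n_perm, seed=int(rng.integers(2**31)))
            p_perm[s] = pp
        else:
            proj = core.build_projection(design)
            f_obs, _, _ = core.pseudo_f(g, proj)
        f_sc, df1, df2 = core.scaled_f(f_obs, spec.n, spec.p, 1)
        p_an[s] = core.analytic_pvalue(f_sc, df1, df2)
    return p_perm, p_an


def level_accuracy_experiment(ns=DEFAULT_LEVEL_NS, p: int = 10,
                              regressor_type: str = "dichotomous",
                              method: str = "permutation",
                              levels=DEFAULT_LEVELS, n_sims: int = 1000,
                              n_perm: int = 999, seed: int = 0,
                              family: str = "normal") -> ExperimentReport:
    """Empirical null rejection rates across nominal levels and sample sizes.

    Under the null (no group effect) an accurate test rejects at nominal
    level alpha a fraction alpha of the time; rates are reported in percent
    per (level, N) cell with binomial standard errors.

    method : {"permutation", "analytic"}
    """
    if method not in ("permutation", "analytic"):
        raise ValueError("method must be 'permutation' or 'analytic'")
    root = np.random.SeedSequence(seed)
    rows = []
    for n, child in zip(ns, root.spawn(len(ns))):
        spec = GeneratorSpec(family=family, n=n, p=p, shift=0.0,
                             regressor_type=regressor_type)
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        pp, pa = _sim_pvalue_pairs(spec, n_sims, n_perm, sub_seed,
                                   want_perm=(method == "permutation"))
        pvals = pp if method == "permutation" else pa
        for level in levels:
            rate = float(np.mean(pvals <= level / 100.0))
            rows.append({"level_pct": level, "n": n, "method": method,
                         "rate": 100.0 * rate,
                         "se": 100.0 * _binom_se(rate, n_sims),
                         "n_sims": n_sims})
    config = {"ns": list(ns), "p": p, "regressor_type": regressor_type,
              "method": method, "levels": list(levels), "n_sims": n_sims,
              "n_perm": n_perm, "family": family}
    return ExperimentReport(pd.DataFrame(rows), config, seed)


def _power_at(spec: GeneratorSpec, alpha: float, n_sims: int, n_perm: int,
              seed: int, method: str = "permutation") -> float:
    pp, pa = _sim_pvalue_pairs(spec, n_sims, n_perm, seed,
                               want_perm=(method == "permutation"))
    pvals = pp if method == "permutation" else pa
    return float(np.mean(pvals <= alpha))


def _threshold(shifts, powers, target: float = 0.80) -> float:
    """Smallest grid shift whose empirical power reaches the target."""
    for s, pw in zip(shifts, powers):
        if pw >= target:
            return float(s)
    return float("nan")


def power_experiment(shifts=DEFAULT_SHIFT_GRID,
                     shifted_fractions=DEFAULT_FRACTIONS, n: int = 30,
                     p: int = 100, alpha: float = 0.05, n_sims: int = 1000,
                     n_perm: int = 999, seed: int = 0,
                     family: str = "normal",
                     stop_after_threshold: bool = False) -> ExperimentReport:
    """Permutation-test power versus group mean shift, per affected fraction.

    Half the samples form the control group; the other half receive the
    shift on the first ceil(fraction * P) variables.  The report's
    ``thresholds`` maps each fraction to the smallest grid shift with
    empirical power >= 0.80.  With ``stop_after_threshold`` the shift grid
    is abandoned once power reaches 80% (the curve is monotone up to
    Monte-Carlo noise), which keeps large scans affordable.
    """
    root = np.random.SeedSequence(seed)
    rows, thresholds = [], {}
    for frac, child in zip(shifted_fractions, root.spawn(len(shifted_fractions))):
        sub = child.generate_state(len(shifts)) % (2**31)
        powers = []
        for shift, s_seed in zip(shifts, sub):
            spec = GeneratorSpec(family=family, n=n, p=p, shift=float(shift),
                                 shifted_fraction=frac,
                                 regressor_type="dichotomous")
            pw = _power_at(spec, alpha, n_sims, n_perm, int(s_seed))
            powers.append(pw)
            rows.append({"shifted_fraction": frac, "shift": float(shift),
                         "method": "permutation", "power": pw,
                         "se": _binom_se(pw, n_sims), "n_sims": n_sims})
            if stop_after_threshold and pw >= 0.80:
                break
        thresholds[frac] = _threshold(shifts[:len(powers)], powers)
    config = {"n": n, "p": p, "alpha": alpha, "n_sims": n_sims,
              "n_perm": n_perm, "family": family,
              "shifts": [float(s) for s in shifts],
              "shifted_fractions": list(shifted_fractions)}
    return ExperimentReport(pd.DataFrame(rows), config, seed, thresholds)


def bonferroni_t_comparator(shifts=DEFAULT_SHIFT_GRID,
                            shifted_fraction: float = 1.0, n: int = 30,
                            p: int = 100, alpha: float = 0.05,
                            n_sims: int = 1000, seed: int = 0,
                            stop_after_threshold: bool = False) -> ExperimentReport:
    """Familywise power of per-variable two-sample t-tests with Bonferroni.

    Per simulated dataset, each of the P variables gets a two-sided
    two-sample t-test; the global null is rejected if any p <= alpha / P.
    """
    rng = np.random.default_rng(seed)
    n0 = n // 2
    n_affected = math.ceil(shifted_fraction * p)
    cut = alpha / p
    rows, powers, used = [], [], []
    for shift in shifts:
        data = rng.standard_normal((n_sims, n, p))
        data[:, n0:, :n_affected] += shift
        res = stats.ttest_ind(data[:, :n0, :], data[:, n0:, :], axis=1)
        reject = np.any(res.pvalue <= cut, axis=1)
        pw = float(np.mean(reject))
        powers.append(pw)
        used.append(float(shift))
        rows.append({"shifted_fraction": shifted_fraction,
                     "shift": float(shift), "method": "bonferroni_t",
                     "power": pw, "se": _binom_se(pw, n_sims),
                     "n_sims": n_sims})
        if stop_after_threshold and pw >= 0.80:
            break
    thresholds = {shifted_fraction: _threshold(used, powers)}
    config = {"n": n, "p": p, "alpha": alpha, "n_sims": n_sims,
              "shifts": [float(s) for s in shifts],
              "shifted_fraction": shifted_fraction}
    return ExperimentReport(pd.DataFrame(rows), config, seed, thresholds)


def bonferroni_power_closed_form(shift: float, n: int = 30, p: int = 100,
                                 alpha: float = 0.05) -> float:
    """Closed-form familywise power for independent variables.

    A single two-sided two-sample t-test at level alpha/P on n/2 vs n/2
    samples has power pi1 under noncentrality shift * sqrt(n0*n1/n); with
    independent variables, P(at least one rejection) = 1 - (1 - pi1)^P
    (pi1 applied to the shifted variables only; unshifted ones reject at
    alpha/P).
    """
    n0 = n // 2
    n1 = n - n0
    df = n - 2
    nc = shift * math.sqrt(n0 * n1 / n)
    tcrit = stats.t.isf(alpha / p / 2.0, df)
    pi1 = float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
    return 1.0 - (1.0 - pi1) ** p


def power_vs_n_experiment(ns=(10, 20, 30, 40, 50, 75, 100),
                          shifts=(0.1, 0.2, 0.3), p: int = 100,
                          alpha: float = 0.05, n_sims: int = 1000,
                          n_perm: int = 999, seed: int = 0,
                          family: str = "normal") -> ExperimentReport:
    """Permutation-test power as sample size grows (half per group)."""
    root = np.random.SeedSequence(seed)
    rows = []
    grid = [(n, s) for n in ns for s in shifts]
    for (n, shift), child in zip(grid, root.spawn(len(grid))):
        spec = GeneratorSpec(family=family, n=n, p=p, shift=shift,
                             shifted_fraction=1.0,
                             regressor_type="dichotomous")
        pw = _power_at(spec, alpha, n_sims, n_perm,
                       int(child.generate_state(1)[0] % (2**31)))
        rows.append({"n": n, "shift": shift, "method": "permutation",
                     "power": pw, "se": _binom_se(pw, n_sims),
                     "n_sims": n_sims})
    config = {"ns": list(ns), "shifts": list(shifts), "p": p, "alpha": alpha,
              "n_sims": n_sims, "n_perm": n_perm, "family": family}
    return ExperimentReport(pd.DataFrame(rows), config, seed)


def continuous_power_experiment(corrs=(0.1, 0.2, 0.3, 0.4),
                                fractions=(0.05, 0.10, 0.15, 0.25, 0.50, 1.0),
                                n: int = 100, p: int = 100,
                                alpha: float = 0.05, n_sims: int = 1000,
                                n_perm: int = 999, seed: int = 0) -> ExperimentReport:
    """Power against a continuous regressor correlated with some variables."""
    root = np.random.SeedSequence(seed)
    rows = []
    grid = [(r, f) for r in corrs for f in fractions]
    for (r, frac), child in zip(grid, root.spawn(len(grid))):
        spec = GeneratorSpec(family="normal", n=n, p=p,
                             regressor_type="continuous", regressor_corr=r,
                             shifted_fraction=frac)
        pw = _power_at(spec, alpha, n_sims, n_perm,
                       int(child.generate_state(1)[0] % (2**31)))
        rows.append({"regressor_corr": r, "fraction": frac,
                     "method": "permutation", "power": pw,
                     "se": _binom_se(pw, n_sims), "n_sims": n_sims})
    config = {"corrs": list(corrs), "fractions": list(fractions), "n": n,
              "p": p, "alpha": alpha, "n_sims": n_sims, "n_perm": n_perm}
    return ExperimentReport(pd.DataFrame(rows), config, seed)


def pvalue_agreement_study(n_range=(100, 100), p_range=(10, 10),
                           n_sims: int = 1000, n_perm: int = 999,
                           seed: int = 0,
                           regressor_type: str = "dichotomous") -> dict:
    """Agreement between permutation and analytic F p-values under the null.

    N and P are drawn uniformly from the given inclusive ranges per
    simulation (fixed when lo == hi).  Returns the per-simulation pairs and
    the Pearson correlation overall and stratified into small (N <= 8) and
    larger samples; a stratum with undefined correlation (fewer than two
    pairs, or zero variance) reports NaN.
    """
    rng = np.random.default_rng(seed)
    recs = []
    for _ in range(n_sims):
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        p = int(rng.integers(p_range[0], p_range[1] + 1))
        if n % 2:  # keep balanced dichotomous groups
            n += 1
        spec = GeneratorSpec(family="normal", n=n, p=p,
                             regressor_type=regressor_type)
        values, x = _draw(rng, spec)
        g = _fast_gower(values)
        design = DesignMatrix(x, ["x"])
        pp, f_obs, _ = core.permutation_test(g, design, n_perm,
                                             seed=int(rng.integers(2**31)))
        f_sc, df1, df2 = core.scaled_f(f_obs, n, p, 1)
        recs.append({"n": n, "p": p, "p_permutation": pp,
                     "p_analytic": core.analytic_pvalue(f_sc, df1, df2)})
    pairs = pd.DataFrame(recs)

    def _r(df: pd.DataFrame) -> float:
        if len(df) < 2:
            return float("nan")
        a, b = df["p_permutation"], df["p_analytic"]
        if a.std() == 0 or b.std() == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    return {
        "pairs": pairs,
        "pearson_r": _r(pairs),
        "pearson_r_small_n": _r(pairs[pairs["n"] <= 8]),
        "pearson_r_large_n": _r(pairs[pairs["n"] > 8]),
        "config": {"n_range": list(n_range), "p_range": list(p_range),
                   "n_sims": n_sims, "n_perm": n_perm,
                   "regressor_type": regressor_type, "seed": seed},
    }
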