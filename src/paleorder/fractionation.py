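"""Two-stage probability model of duplicate/triplicate gene loss after
genome tripling.

After a hexaploidization at time ``t0`` every gene family has three copies.
Redundant copies are lost independently with probability ``p`` on the shared
branch to the radiation at ``t1`` (total loss of a family prohibited), then
with lineage-specific probability ``q_i`` between ``t1`` and the present
``t2`` (again conditioned on survival).  Writing ``P3, P2, P1`` for the
stage-1 family-size probabilities,

    P3 = (1-p)^3 / (1-p^3)
    P2 = 3p(1-p)^2 / (1-p^3)
    P1 = 3p^2(1-p) / (1-p^3)

the present-day probabilities that an original triplet survives as a
triplet ``T``, a pair ``D`` or a single copy ``S`` in lineage *i* are

    T = P3 * (1-q)^3/(1-q^3)
    D = P3 * 3q(1-q)^2/(1-q^3) + P2 * (1-q)^2/(1-q^2)
    S = P3 * 3q^2(1-q)/(1-q^3) + P2 * 2q(1-q)/(1-q^2) + P1

with ``q = q_i``.  Each stage's probabilities sum to one exactly.

Because observed family-size tables typically report only sizes two and
three (singles are indistinguishable from never-duplicated genes), the
default likelihood conditions on family size in {2, 3}: the triple count is
binomial with success probability ``T/(T+D)``.  That conditional likelihood
identifies only the per-lineage ratio ``T_i/(T_i+D_i)``, partially
confounding ``p`` with the ``q_i``; the fitted ratios are well determined
while the split between the two stages is reported as profile-flat.  A full
multinomial likelihood is available when single-copy counts and the original
triplet number ``N`` are known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "stage1_probs",
    "stage2_probs",
    "predict_counts",
    "model_curves",
    "simulate_stage_probs",
    "simulate_family_counts",
    "FractionationParams",
    "FractionationModel",
    "FractionationResults",
]


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value < 1.0):
        raise ValueError(f"{name} must lie in [0, 1), got {value!r}")


def stage1_probs(p: float) -> tuple[float, float, float]:
    """Family-size probabilities (P3, P2, P1) after the shared-branch stage."""
    _check_prob("p", p)
    if p == 0.0:
        return 1.0, 0.0, 0.0
    denom = 1.0 - p ** 3
    one = 1.0 - p
    return (
        one ** 3 / denom,
        3.0 * p * one ** 2 / denom,
        3.0 * p ** 2 * one / denom,
    )


def stage2_probs(p: float, q: float) -> tuple[float, float, float]:
    """Present-day (T, D, S) probabilities for one lineage."""
    _check_prob("p", p)
    _check_prob("q", q)
    p3, p2, p1 = stage1_probs(p)
    if q == 0.0:
        return p3, p2, p1
    d3 = 1.0 - q ** 3
    d2 = 1.0 - q ** 2
    one = 1.0 - q
    t = p3 * one ** 3 / d3
    d = p3 * 3.0 * q * one ** 2 / d3 + p2 * one ** 2 / d2
    s = p3 * 3.0 * q ** 2 * one / d3 + p2 * 2.0 * q * one / d2 + p1
    return t, d, s


@dataclass(frozen=True)
class FractionationParams:
    """Parameters of the two-stage loss model."""

    p: float
    q: Mapping[str, float]  # lineage -> post-radiation loss probability
    N: int = 1              # original triplet count

    def __post_init__(self) -> None:
        _check_prob("p", self.p)
        for lineage, qi in self.q.items():
            _check_prob(f"q[{lineage}]", qi)
        if self.N < 0:
            raise ValueError(f"N must be >= 0, got {self.N}")


def predict_counts(params: FractionationParams) -> pd.DataFrame:
    """Expected (triples, pairs, singles) per lineage; rows sum to N."""
    rows = {}
    for lineage in sorted(params.q):
        t, d, s = stage2_probs(params.p, params.q[lineage])
        rows[lineage] = (params.N * t, params.N * d, params.N * s)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["triples", "pairs", "singles"]
    ).rename_axis("lineage")


def model_curves(
    p: float,
    q_grid: Sequence[float],
    N_values: Sequence[int],
) -> pd.DataFrame:
    """Loci of expected (pairs, triples) points across q for each N.

    Each curve traces how a lineage with ``N`` original triplets moves
    through the pair/triple plane as its post-radiation loss probability
    grows; observed genomes can be compared against the family of curves.
    """
    rows = []
    for n in N_values:
        for q in q_grid:
            t, d, _ = stage2_probs(p, q)
            rows.append({"N": n, "q": q, "pairs": n * d, "triples": n * t})
    return pd.DataFrame(rows)


def plot_model_curves(curves: pd.DataFrame, observed: pd.DataFrame | None = None, ax=None):
    """Plot (pairs, triples) model curves, optionally with observed points."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for n, grp in curves.groupby("N"):
        ax.plot(grp["pairs"], grp["triples"], label=f"N={n}")
    if observed is not None:
        ax.scatter(observed["n_pairs"], observed["n_triples"], c="k", zorder=3)
        for lineage, row in observed.iterrows():
            ax.annotate(str(lineage), (row["n_pairs"], row["n_triples"]))
    ax.set_xlabel("duplicate families")
    ax.set_ylabel("triplicate families")
    ax.legend()
    return ax


# ---------------------------------------------------------------------------
# Monte-Carlo oracle


def simulate_stage_probs(
    p: float,
    q: float,
    reps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional survival simulation of the two-stage loss process.

    Independent of the closed forms: draws per-copy losses and resamples any
    family that would lose all copies at either stage.  Returns the stage-1
    size distribution [P3hat, P2hat, P1hat] and the stage-2 distribution
    [That, Dhat, Shat].
    """
    _check_prob("p", p)
    _check_prob("q", q)
    survive1 = rng.random((reps, 3)) >= p
    dead = ~survive1.any(axis=1)
    while dead.any():
        survive1[dead] = rng.random((int(dead.sum()), 3)) >= p
        dead = ~survive1.any(axis=1)
    sizes1 = survive1.sum(axis=1)
    stage1 = np.array([(sizes1 == k).mean() for k in (3, 2, 1)])

    survive2 = survive1 & (rng.random((reps, 3)) >= q)
    redo = (~survive2.any(axis=1)) & (sizes1 > 1)
    while redo.any():
        idx = np.flatnonzero(redo)
        survive2[idx] = survive1[idx] & (rng.random((len(idx), 3)) >= q)
        redo[idx] = ~survive2[idx].any(axis=1)
    # single-copy families carry no redundancy: the survivor is never lost
    survive2[sizes1 == 1] = survive1[sizes1 == 1]
    sizes2 = survive2.sum(axis=1)
    stage2 = np.array([(sizes2 == k).mean() for k in (3, 2, 1)])
    return stage1, stage2


def simulate_family_counts(
    params: FractionationParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw observed (n_triples, n_pairs, n_singles) per lineage from the model."""
    rows = {}
    for lineage in sorted(params.q):
        probs = stage2_probs(params.p, params.q[lineage])
        rows[lineage] = rng.multinomial(params.N, probs)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["n_triples", "n_pairs", "n_singles"]
    ).rename_axis("lineage")


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting


def _unpack(theta: np.ndarray) -> tuple[float, np.ndarray]:
    # logistic transform keeps parameters in (0, 1); clip avoids overflow at
    # the boundary when the optimizer wanders far out
    probs = 1.0 / (1.0 + np.exp(-np.clip(theta, -35.0, 35.0)))
    return float(probs[0]), probs[1:]


class FractionationModel:
    """Maximum-likelihood model for observed gene-family-size counts.

    Parameters
    ----------
    counts:
        DataFrame indexed by lineage with columns ``n_triples``, ``n_pairs``
        and optionally ``n_singles``.
    likelihood:
        ``"conditional"`` (default) conditions on family size in {2, 3};
        ``"multinomial"`` uses triples/pairs/singles jointly and requires
        ``N`` (the original triplet count) — supplied here or inferred as
        the per-lineage row sum.
    N:
        Original triplet count for the multinomial likelihood.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        likelihood: str = "conditional",
        N: int | None = None,
    ):
        if likelihood not in ("conditional", "multinomial"):
            raise ValueError(f"unknown likelihood {likelihood!r}")
        if counts.empty:
            raise ValueError("no lineage counts supplied")
        required = ["n_triples", "n_pairs"]
        missing = [c for c in required if c not in counts.columns]
        if missing:
            raise ValueError(f"counts missing columns {missing}")
        if likelihood == "multinomial" and "n_singles" not in counts.columns:
            raise ValueError("multinomial likelihood needs an n_singles column")
        counts = counts.sort_index()
        if (counts["n_triples"] + counts["n_pairs"] == 0).any():
            raise ValueError("a lineage with zero observed pairs and triples is degenerate")
        self.counts = counts
        self.likelihood = likelihood
        self.lineages = list(counts.index)
        if likelihood == "multinomial" and N is None:
            row_sums = counts[["n_triples", "n_pairs", "n_singles"]].sum(axis=1)
            if row_sums.nunique() != 1:
                raise ValueError(
                    "cannot infer N: per-lineage totals differ; pass N explicitly"
                )
            N = int(row_sums.iloc[0])
        self.N = N

    @classmethod
    def from_dataframe(
        cls, counts: pd.DataFrame, **kwargs
    ) -> "FractionationModel":
        if "lineage" in counts.columns:
            counts = counts.set_index("lineage")
        return cls(counts, **kwargs)

    def loglike(self, p: float, q: Mapping[str, float]) -> float:
        ll = 0.0
        for lineage, row in self.counts.iterrows():
            t, d, s = stage2_probs(p, q[lineage])
            n3, n2 = int(row["n_triples"]), int(row["n_pairs"])
            if self.likelihood == "conditional":
                ratio = t / (t + d)
                ll += float(stats.binom.logpmf(n3, n3 + n2, ratio))
            else:
                n1 = int(row["n_singles"])
                ll += float(
                    stats.multinomial.logpmf([n3, n2, n1], n=n3 + n2 + n1, p=[t, d, s])
                )
        return ll

    def _negloglike(self, theta: np.ndarray) -> float:
        p, qs = _unpack(theta)
        q = dict(zip(self.lineages, qs))
        ll = self.loglike(p, q)
        return np.inf if not np.isfinite(ll) else -ll

    def fit(
        self,
        start_grid: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
    ) -> "FractionationResults":
        """Multi-start quasi-Newton maximisation over (p, q_1..q_L).

        The start grid is fixed, so the fit is deterministic.  The best of
        all converged starts wins; ties go to the first encountered.
        """
        n_q = len(self.lineages)
        best = None
        for p0 in start_grid:
            for q0 in start_grid:
                theta0 = np.concatenate(
                    [[np.log(p0 / (1 - p0))], np.full(n_q, np.log(q0 / (1 - q0)))]
                )
                res = optimize.minimize(
                    self._negloglike, theta0, method="Nelder-Mead",
                    options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-12},
                )
                if best is None or res.fun < best.fun - 1e-12:
                    best = res
        p_hat, q_hat = _unpack(best.x)
        params = FractionationParams(
            p=p_hat,
            q=dict(zip(self.lineages, (float(v) for v in q_hat))),
            N=self.N if self.N is not None else 1,
        )
        return FractionationResults(self, params, llf=-float(best.fun))


@dataclass
class FractionationResults:
    """Fit results: parameter estimates, fitted ratios, diagnostics."""

    model: FractionationModel
    params: FractionationParams
    llf: float
    _profile: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def fitted_ratios(self) -> pd.Series:
        """Identifiable quantity per lineage: T/(T+D)."""
        vals = {}
        for lineage in self.model.lineages:
            t, d, _ = stage2_probs(self.params.p, self.params.q[lineage])
            vals[lineage] = t / (t + d)
        return pd.Series(vals, name="triple_share")

    @property
    def observed_ratios(self) -> pd.Series:
        c = self.model.counts
        return (c["n_triples"] / (c["n_triples"] + c["n_pairs"])).rename("triple_share")

    @property
    def ratio_se(self) -> pd.Series:
        """Binomial standard error of the observed triple share."""
        c = self.model.counts
        n = c["n_triples"] + c["n_pairs"]
        r = self.fitted_ratios
        return np.sqrt(r * (1 - r) / n).rename("se")

    def predict(self, N: int | None = None) -> pd.DataFrame:
        params = self.params
        if N is not None:
            params = FractionationParams(params.p, dict(params.q), N)
        return predict_counts(params)

    def profile_p(self, grid: Sequence[float] | None = None) -> pd.DataFrame:
        """Profile log-likelihood over p (q_i re-optimised at each point).

        Under the conditional likelihood the profile is flat wherever every
        lineage ratio stays reachable, which quantifies the p/q confounding.
        """
        if self._profile is not None and grid is None:
            return self._profile
        if grid is None:
            grid = np.linspace(0.02, 0.95, 20)
        rows = []
        n_q = len(self.model.lineages)
        for p in grid:
            def nll(theta_q: np.ndarray, p=p) -> float:
                qs = 1.0 / (1.0 + np.exp(-np.clip(theta_q, -35.0, 35.0)))
                q = dict(zip(self.model.lineages, qs))
                ll = self.model.loglike(p, q)
                return np.inf if not np.isfinite(ll) else -ll

            start = np.full(n_q, 0.0)
            res = optimize.minimize(nll, start, method="Nelder-Mead",
                                    options={"maxiter": 2000})
            rows.append({"p": p, "llf": -res.fun})
        self._profile = pd.DataFrame(rows)
        return self._profile

    @property
    def identifiability_flat(self) -> bool:
        """True when the profile over p is flat to within 0.01 log-units."""
        prof = self.profile_p()
        return bool(prof["llf"].max() - prof["llf"].min() < 1e-2)

    def summary(self) -> str:
        lines = [
            "Two-stage fractionation model",
            "=============================",
            f"likelihood:        {self.model.likelihood}",
            f"lineages:          {len(self.model.lineages)}",
            f"log-likelihood:    {self.llf:.4f}",
            f"p (shared stage):  {self.params.p:.4f}",
            "",
            "lineage      q_i     T/(T+D) fit   T/(T+D) obs      se",
        ]
        obs = self.observed_ratios
        fit = self.fitted_ratios
        se = self.ratio_se
        for lineage in self.model.lineages:
            lines.append(
                f"{str(lineage):<10} {self.params.q[lineage]:7.4f}   "
                f"{fit[lineage]:11.4f}   {obs[lineage]:11.4f} {se[lineage]:7.4f}"
            )
        lines.append("")
        lines.append(
            "note: the conditional likelihood identifies T/(T+D) per lineage; "
            "p and q_i are partially confounded (see profile_p())."
        )
        return "\n".join(lines)
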