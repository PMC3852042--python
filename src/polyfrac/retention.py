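"""Two-class maximum-likelihood model of paralog retention after triplication.

The model follows the fate of N ancestral genes, each triplicated by a
whole-genome triplication.  Every copy survives a shared pre-speciation
fractionation phase with probability 1-p, then survives independently in
species i with probability 1-q_i.  Genes fall into two rate classes: a
fraction theta with rates (p, q_i) and a fraction 1-theta with rates
(alpha*p, alpha*q_i), alpha <= 1 by labelling convention, so the theta class
is the faster-fractionating (fractionation-prone) one.

Because a copy's overall survival probability is s = (1-p)(1-q_i), the
number of surviving copies of a triplet in species i is Binomial(3, s); the
observed data are the per-species counts of surviving pairs (n2) and triples
(n3), with single-copy and extinct families unobserved and pooled into a
remainder category of size N - n2 - n3.  The likelihood is the product over
species of the multinomial mass of (n3, n2, remainder) under the two-class
mixture of those binomial probabilities.  Species are treated as independent
even though the shared pre-speciation phase correlates them; this mirrors
the model's intended use on per-species marginal counts.

A caution that matters in practice: the category probabilities depend on
(p, q_i, alpha) only through the per-copy survival products, so the
likelihood surface carries a long, nearly flat ridge in (theta, alpha) and
point estimates of the mixture structure are weakly identified.  The fit
reports all multistart solutions so the flatness is visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln
from scipy.stats import qmc

__all__ = [
    "RetentionParams",
    "RetentionPMF",
    "RetentionCounts",
    "RetentionModel",
    "RetentionResults",
    "retention_pmf",
    "mixture_pmf",
    "predict_score_distribution",
    "load_rosid_counts",
]


@dataclass(frozen=True)
class RetentionParams:
    """Model parameters; ``q`` is ordered like the species of the counts."""

    p: float
    q: tuple[float, ...]
    theta: float
    alpha: float
    n_ancestral: int

    def __post_init__(self) -> None:
        vals = (self.p, *self.q, self.theta)
        if not all(0.0 <= v <= 1.0 for v in vals):
            raise ValueError("p, q_i and theta must lie in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.alpha * self.p > 1 + 1e-12 or any(
            self.alpha * qi > 1 + 1e-12 for qi in self.q
        ):
            raise ValueError("alpha*p and alpha*q_i must not exceed 1")
        if self.n_ancestral < 0:
            raise ValueError("n_ancestral must be non-negative")

    @property
    def n_species(self) -> int:
        return len(self.q)

    def swapped(self) -> "RetentionParams":
        """The label-switched equivalent parameterisation (alpha -> 1/alpha)."""
        a = self.alpha
        return RetentionParams(
            p=a * self.p,
            q=tuple(a * qi for qi in self.q),
            theta=1.0 - self.theta,
            alpha=1.0 / a,
            n_ancestral=self.n_ancestral,
        )


@dataclass(frozen=True)
class RetentionPMF:
    """Per-species retention category probabilities for one triplet."""

    P3: float
    P2: float
    P1: float
    P0: float
    s: float  # per-copy overall survival (1-p)(1-q); mixtures report the mean

    def as_array(self) -> np.ndarray:
        return np.array([self.P3, self.P2, self.P1, self.P0])


def retention_pmf(p: float, q: float) -> RetentionPMF:
    """Category probabilities for a single rate class.

    Written out phase by phase (all-three-survive-phase-1 terms first), which
    collapses algebraically to Binomial(3, s) with s = (1-p)(1-q).
    """
    if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
        raise ValueError("p and q must lie in [0, 1]")
    P3 = (1 - p) ** 3 * (1 - q) ** 3
    P2 = (1 - p) ** 3 * 3 * q * (1 - q) ** 2 + 3 * p * (1 - p) ** 2 * (1 - q) ** 2
    P1 = (
        (1 - p) ** 3 * 3 * q**2 * (1 - q)
        + 3 * p * (1 - p) ** 2 * 2 * q * (1 - q)
        + 3 * p**2 * (1 - p) * (1 - q)
    )
    P0 = 1.0 - P3 - P2 - P1
    return RetentionPMF(P3, P2, P1, P0, (1 - p) * (1 - q))


def mixture_pmf(params: RetentionParams, i: int) -> RetentionPMF:
    """Two-class mixture of retention categories for species ``i``."""
    th = params.theta
    a = retention_pmf(params.p, params.q[i])
    b = retention_pmf(params.alpha * params.p, params.alpha * params.q[i])
    mix = th * a.as_array() + (1 - th) * b.as_array()
    return RetentionPMF(*mix, s=th * a.s + (1 - th) * b.s)


@dataclass(frozen=True)
class RetentionCounts:
    """Observed per-species numbers of surviving pairs and triples."""

    species: tuple[str, ...]
    n2: tuple[int, ...]
    n3: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.species) == len(self.n2) == len(self.n3)):
            raise ValueError("species, n2 and n3 must have equal length")
        if any(v < 0 for v in (*self.n2, *self.n3)):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RetentionCounts":
        need = {"species", "n2", "n3"}
        if not need <= set(df.columns):
            raise ValueError(f"counts table needs columns {sorted(need)}")
        return cls(
            species=tuple(df["species"].astype(str)),
            n2=tuple(int(v) for v in df["n2"]),
            n3=tuple(int(v) for v in df["n3"]),
        )

    @classmethod
    def from_tsv(cls, path) -> "RetentionCounts":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": self.species, "n2": self.n2, "n3": self.n3}
        )

    @property
    def n_species(self) -> int:
        return len(self.species)


def load_rosid_counts() -> RetentionCounts:
    """The six-rosid pair/triple counts shipped with the package."""
    with resources.files("polyfrac.data").joinpath(
        "rosid_pair_triple_counts.tsv"
    ).open() as fh:
        return RetentionCounts.from_dataframe(pd.read_csv(fh, sep="\t"))


class RetentionModel:
    """Maximum-likelihood fit of the two-class retention model.

    Parameters
    ----------
    counts
        Observed pair/triple counts per species (a :class:`RetentionCounts`
        or a DataFrame with columns species, n2, n3).
    n_ancestral
        Assumed number of ancestral pre-triplication genes N; must be at
        least the largest per-species n2+n3.

    Examples
    --------
    >>> model = RetentionModel(load_rosid_counts(), n_ancestral=7500)
    >>> res = model.fit(seed=1)
    >>> round(res.params.alpha, 2)  # doctest: +SKIP
    """

    def __init__(self, counts, n_ancestral: int = 7500):
        if isinstance(counts, pd.DataFrame):
            counts = RetentionCounts.from_dataframe(counts)
        self.counts = counts
        self.n_ancestral = int(n_ancestral)
        totals = np.asarray(counts.n2) + np.asarray(counts.n3)
        if self.n_ancestral < totals.max():
            raise ValueError(
                "n_ancestral must be at least the largest per-species n2+n3 "
                f"({totals.max()})"
            )
        self._n2 = np.asarray(counts.n2, dtype=float)
        self._n3 = np.asarray(counts.n3, dtype=float)
        self._S = counts.n_species
        # multinomial normalising constants (parameter-free)
        N = float(self.n_ancestral)
        rest = N - self._n2 - self._n3
        self._log_const = float(
            np.sum(
                gammaln(N + 1)
                - gammaln(self._n3 + 1)
                - gammaln(self._n2 + 1)
                - gammaln(rest + 1)
            )
        )

    # -- likelihood ---------------------------------------------------------

    def _category_probs(self, x: np.ndarray):
        """(P3, P2, remainder) per species for packed parameters ``x``.

        ``x`` packs (p, q_1..q_S, theta, alpha).
        """
        p, th, al = x[0], x[-2], x[-1]
        q = x[1 : 1 + self._S]
        s1 = (1 - p) * (1 - q)
        s2 = (1 - al * p) * (1 - al * q)
        P3 = th * s1**3 + (1 - th) * s2**3
        P2 = th * 3 * s1**2 * (1 - s1) + (1 - th) * 3 * s2**2 * (1 - s2)
        return P3, P2, 1.0 - P3 - P2

    def loglike(self, params: RetentionParams) -> float:
        """Multinomial log-likelihood (combinatorial constants included)."""
        x = np.array([params.p, *params.q, params.theta, params.alpha])
        P3, P2, rest = self._category_probs(x)
        terms = []
        for n, P in ((self._n3, P3), (self._n2, P2), (self.n_ancestral - self._n3 - self._n2, rest)):
            n = np.asarray(n, dtype=float)
            with np.errstate(divide="ignore"):
                logP = np.log(P)
            bad = (n > 0) & (P <= 0)
            if bad.any():
                return -math.inf
            pos = n > 0
            terms.append(np.sum(n[pos] * logP[pos]))
        return self._log_const + float(sum(terms))

    def _neg_loglike_packed(self, x: np.ndarray) -> float:
        P3, P2, rest = self._category_probs(x)
        if np.any(P3 <= 0) or np.any(P2 <= 0) or np.any(rest <= 0):
            return 1e15
        ll = np.sum(
            self._n3 * np.log(P3)
            + self._n2 * np.log(P2)
            + (self.n_ancestral - self._n3 - self._n2) * np.log(rest)
        )
        return -(self._log_const + ll)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        seed: int = 0,
        n_starts: int = 32,
        start_params: Optional[RetentionParams] = None,
    ) -> "RetentionResults":
        """Maximise the likelihood with seeded Latin-hypercube multistart.

        All parameters are box-constrained to (0, 1); together with the
        alpha <= 1 labelling convention this keeps alpha*p and alpha*q_i in
        range automatically.  Returns the best local optimum plus the full
        per-start table.
        """
        d = self._S + 3
        eps = 1e-9
        bounds = [(eps, 1 - eps)] * d
        sampler = qmc.LatinHypercube(d=d, seed=int(seed) % (2**31))
        starts = sampler.random(n_starts) * 0.96 + 0.02
        if start_params is not None:
            sp = np.array(
                [start_params.p, *start_params.q, start_params.theta, start_params.alpha]
            )
            starts = np.vstack([sp, starts])
        rows = []
        best = None
        for x0 in starts:
            r = optimize.minimize(
                self._neg_loglike_packed,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 5000},
            )
            rows.append((*x0, -r.fun, bool(r.success)))
            if r.success and (best is None or r.fun < best.fun):
                best = r
        if best is None:
            raise RuntimeError("no multistart converged; see per-start table")
        x = best.x
        params = RetentionParams(
            p=float(x[0]),
            q=tuple(float(v) for v in x[1 : 1 + self._S]),
            theta=float(x[-2]),
            alpha=float(x[-1]),
            n_ancestral=self.n_ancestral,
        )
        starts_df = pd.DataFrame(
            rows,
            columns=[
                "start_p",
                *[f"start_q_{s}" for s in self.counts.species],
                "start_theta",
                "start_alpha",
                "loglike",
                "converged",
            ],
        )
        bse = self._standard_errors(x)
        return RetentionResults(
            model=self,
            params=params,
            llf=float(-best.fun),
            converged=True,
            n_starts=len(starts),
            starts=starts_df,
            bse=bse,
            seed=int(seed),
        )

    def _standard_errors(self, x: np.ndarray) -> np.ndarray:
        """Observed-information SEs via central-difference Hessian.

        Entries are NaN when the Hessian is not positive definite in that
        direction (typical when a parameter sits on the boundary or on the
        flat (theta, alpha) ridge).
        """
        d = len(x)
        h = 1e-5
        H = np.zeros((d, d))
        f = self._neg_loglike_packed

        def clip(v):
            return np.clip(v, 1e-9, 1 - 1e-9)

        f0 = f(x)
        for i in range(d):
            for j in range(i, d):
                xi = x.copy()
                if i == j:
                    xp, xm = x.copy(), x.copy()
                    xp[i] += h
                    xm[i] -= h
                    H[i, i] = (f(clip(xp)) - 2 * f0 + f(clip(xm))) / h**2
                else:
                    vals = []
                    for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                        xv = x.copy()
                        xv[i] += si * h
                        xv[j] += sj * h
                        vals.append(f(clip(xv)))
                    H[i, j] = H[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (
                        4 * h**2
                    )
        with np.errstate(invalid="ignore"):
            try:
                cov = np.linalg.inv(H)
                se = np.sqrt(np.diag(cov))
            except np.linalg.LinAlgError:
                se = np.full(d, np.nan)
        se[~np.isfinite(se)] = np.nan
        return se


@dataclass
class RetentionResults:
    """Fit results: estimates, uncertainties, diagnostics, predictions."""

    model: RetentionModel
    params: RetentionParams
    llf: float
    converged: bool
    n_starts: int
    starts: pd.DataFrame
    bse: np.ndarray
    seed: int

    @property
    def larger_class_share(self) -> float:
        """max(theta, 1-theta): the share of genes in the larger class."""
        return max(self.params.theta, 1.0 - self.params.theta)

    def param_names(self) -> list[str]:
        return ["p", *[f"q_{s}" for s in self.model.counts.species], "theta", "alpha"]

    def params_series(self) -> pd.Series:
        x = [self.params.p, *self.params.q, self.params.theta, self.params.alpha]
        return pd.Series(x, index=self.param_names())

    def summary(self) -> str:
        est = self.params_series()
        lines = [
            "Two-class paralog retention model",
            "=" * 46,
            f"species:            {', '.join(self.model.counts.species)}",
            f"N ancestral genes:  {self.model.n_ancestral}",
            f"log-likelihood:     {self.llf:.3f}",
            f"multistarts:        {self.n_starts} (seed {self.seed})",
            f"larger class share: {100 * self.larger_class_share:.1f}%",
            "-" * 46,
            f"{'param':<14}{'estimate':>10}{'std err':>12}",
        ]
        for name, value, se in zip(self.param_names(), est, self.bse):
            se_txt = f"{se:12.4f}" if np.isfinite(se) else f"{'--':>12}"
            lines.append(f"{name:<14}{value:10.4f}{se_txt}")
        lines.append("-" * 46)
        lines.append(
            "labelling: alpha <= 1, so the theta class fractionates faster"
        )
        return "\n".join(lines)

    def expected_counts(self) -> pd.DataFrame:
        """Fitted expected n2/n3 per species next to the observed counts."""
        x = np.array(
            [self.params.p, *self.params.q, self.params.theta, self.params.alpha]
        )
        P3, P2, _ = self.model._category_probs(x)
        N = self.model.n_ancestral
        return pd.DataFrame(
            {
                "species": self.model.counts.species,
                "n2_obs": self.model.counts.n2,
                "n2_fit": N * P2,
                "n3_obs": self.model.counts.n3,
                "n3_fit": N * P3,
            }
        )

    def profile_over_n(
        self, n_values: Sequence[int], seed: Optional[int] = None
    ) -> pd.DataFrame:
        """Refit at each ancestral gene count N and tabulate parameter drift."""
        seed = self.seed if seed is None else seed
        rows = []
        for N in n_values:
            res = RetentionModel(self.model.counts, n_ancestral=int(N)).fit(
                seed=seed, n_starts=self.n_starts
            )
            row = {"N": int(N), "loglike": res.llf}
            row.update(res.params_series().to_dict())
            row["larger_class_share"] = res.larger_class_share
            rows.append(row)
        return pd.DataFrame(rows)

    def predict_score_distribution(
        self, species: Optional[Sequence[str]] = None
    ) -> pd.DataFrame:
        """Predicted fractionation-score distribution per class (see below)."""
        return predict_score_distribution(self.model.counts, self.params, species)


def predict_score_distribution(
    counts: RetentionCounts,
    params: RetentionParams,
    species: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Predicted per-class fractionation-score distribution over G genomes.

    Conditions on the gene surviving (>= 1 copy) in every genome of the
    subset, as full homology sets do.  Within each class, genome i is
    multi-copy with probability m_i = (P3+P2)/(P3+P2+P1); the score over G
    genomes is the Poisson-binomial of those indicators.  Expected gene
    counts scale by N, the class share and the probability of surviving in
    all G genomes; ``proportion`` gives the relative weight of each class at
    each score (the two predicted retention-pattern curves).
    """
    all_species = list(counts.species)
    if species is None:
        species = all_species
    idx = []
    for sp in species:
        if sp not in all_species:
            raise KeyError(f"unknown species {sp!r}")
        idx.append(all_species.index(sp))
    G = len(idx)

    rows = []
    per_class = {}
    for label, p_eff, q_all, share in (
        ("prone", params.p, params.q, params.theta),
        ("resistant", params.alpha * params.p,
         tuple(params.alpha * qi for qi in params.q), 1 - params.theta),
    ):
        m = []
        surv = 1.0
        for i in idx:
            pmf = retention_pmf(p_eff, q_all[i])
            alive = pmf.P3 + pmf.P2 + pmf.P1
            if alive <= 0:
                raise ZeroDivisionError(
                    f"class {label}: survival probability 0 in species "
                    f"{all_species[i]}; score distribution undefined"
                )
            m.append((pmf.P3 + pmf.P2) / alive)
            surv *= alive
        # Poisson-binomial over the G multi-copy indicators
        dist = np.zeros(G + 1)
        dist[0] = 1.0
        for mi in m:
            dist[1:] = dist[1:] * (1 - mi) + dist[:-1] * mi
            dist[0] *= 1 - mi
        per_class[label] = (dist, share * surv)
        for k in range(G + 1):
            rows.append(
                {
                    "class": label,
                    "score": k,
                    "probability": dist[k],
                    "expected_genes": params.n_ancestral * share * surv * dist[k],
                }
            )
    df = pd.DataFrame(rows)
    totals = df.groupby("score")["expected_genes"].transform("sum")
    with np.errstate(invalid="ignore"):
        df["proportion"] = np.where(
            totals > 0, df["expected_genes"] / totals, np.nan
        )
    return df
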