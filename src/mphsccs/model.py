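"""Conditional Poisson regression for the self-controlled case series design.

Conditioning each case's Poisson interval counts on that case's event total
turns the likelihood into a product of per-patient multinomials: given the
patient's intervals with lengths :math:`t_{ij}` and covariate rows
:math:`x_{ij}`, the probability that the events fall where they did is

.. math::

    \\ell(\\beta) = \\sum_i \\sum_j n_{ij} \\log
        \\frac{t_{ij} e^{x_{ij}\\beta}}{\\sum_k t_{ik} e^{x_{ik}\\beta}}

so all between-person (time-invariant) confounding cancels.  Exponentiated
coefficients are incidence rate ratios relative to baseline person-time.

The fit is a plain Newton-Raphson on the exact analytic gradient and Hessian,
started from zero, with step-halving; patients whose intervals all share one
covariate pattern contribute a constant and are dropped (counted in
``n_dropped_noninformative``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import AnalysisInterval

INTERVAL_COLUMNS = ["patient_id", "category", "age_band", "season", "length_days", "events"]

_CAT_TO_NAME = {0: "baseline", 1: "pre_exposure", 2: "exposed"}


class EstimationError(RuntimeError):
    """The model cannot be estimated (no within-person contrast, or singular)."""


def _fmt2(value: float) -> str:
    """Two decimals with conventional half-up rounding (1.015 -> '1.02')."""
    from decimal import ROUND_HALF_UP, Decimal

    return str(Decimal(repr(float(value))).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass(frozen=True)
class IrrEstimate:
    """One reported incidence rate ratio with its Wald interval."""

    term: str
    irr: float
    ci_low: float
    ci_high: float
    p_value: float

    def format_irr_ci(self) -> str:
        return f"{_fmt2(self.irr)} | {_fmt2(self.ci_low)}–{_fmt2(self.ci_high)}"

    def format_p(self) -> str:
        return "<0.01" if self.p_value < 0.01 else _fmt2(self.p_value)


def intervals_to_frame(intervals: Sequence[AnalysisInterval]) -> pd.DataFrame:
    """Flatten record-level intervals into the model's input table."""
    return pd.DataFrame(
        {
            "patient_id": [iv.patient_id for iv in intervals],
            "category": [iv.category.value for iv in intervals],
            "age_band": [iv.age_band for iv in intervals],
            "season": [iv.season for iv in intervals],
            "length_days": [iv.length_days for iv in intervals],
            "events": [iv.events for iv in intervals],
        }
    )


class SCCSModel:
    """Self-controlled case series model on a table of analysis intervals.

    Parameters
    ----------
    intervals
        DataFrame with columns ``patient_id, category, age_band, season,
        length_days, events`` (one row per interval; ``category`` is
        ``baseline`` / ``pre_exposure`` / ``exposed``), or a sequence of
        :class:`~mphsccs.segmentation.AnalysisInterval`.
    adjust_age, adjust_season
        Include indicator terms for observed age bands / seasons.  The
        reference level is the baseline category, the earliest observed age
        band, and season 1 (or the earliest observed season); exposure IRRs
        are invariant to this corner-point choice.
    """

    def __init__(self, intervals, adjust_age: bool = True, adjust_season: bool = True):
        if not isinstance(intervals, pd.DataFrame):
            intervals = intervals_to_frame(list(intervals))
        missing = [c for c in INTERVAL_COLUMNS if c not in intervals.columns]
        if missing:
            raise ValueError(f"interval table missing column(s) {missing}")
        self.intervals = intervals.reset_index(drop=True)
        self.adjust_age = adjust_age
        self.adjust_season = adjust_season
        self._build_design()

    # -- design ------------------------------------------------------------

    def _build_design(self) -> None:
        df = self.intervals
        if (df["length_days"] <= 0).any():
            raise ValueError("interval lengths must be positive")
        cat_raw = df["category"]
        if cat_raw.dtype == object:
            name_to_code = {"baseline": 0, "pre_exposure": 1, "exposed": 2}
            mapped = cat_raw.map(name_to_code)
            if mapped.isna().any():
                bad = sorted(set(cat_raw) - set(name_to_code))
                raise ValueError(f"unknown exposure categories: {bad}")
            cat = mapped.to_numpy(dtype=np.int8)
        else:
            cat = cat_raw.to_numpy(dtype=np.int8)

        pid, patient_index = np.unique(df["patient_id"].to_numpy(), return_inverse=True)
        order = np.argsort(patient_index, kind="stable")
        self._row_order = order
        self._pid = pid
        g = patient_index[order]
        self._group_starts = np.concatenate(([0], np.flatnonzero(np.diff(g)) + 1))
        self._group_ids = g

        cat = cat[order]
        band = df["age_band"].to_numpy(dtype=np.int64)[order]
        season = df["season"].to_numpy(dtype=np.int64)[order]
        self._t = df["length_days"].to_numpy(dtype=np.float64)[order]
        self._n = df["events"].to_numpy(dtype=np.float64)[order]

        cols: list[np.ndarray] = []
        names: list[str] = []
        for code, label in ((1, "pre_exposure"), (2, "exposed")):
            if np.any(cat == code):
                cols.append((cat == code).astype(np.float64))
                names.append(label)
        self.exposure_terms = list(names)
        if self.adjust_age:
            bands = np.unique(band)
            for b in bands[1:]:  # earliest observed band is the reference
                cols.append((band == b).astype(np.float64))
                names.append(f"age[{int(b)}]")
        if self.adjust_season:
            seasons = np.unique(season)
            for s in seasons[1:]:  # season 1 (or earliest observed) is the reference
                cols.append((season == s).astype(np.float64))
                names.append(f"season[{int(s)}]")
        if not cols:
            raise EstimationError("no estimable terms in the design")
        self._X = np.column_stack(cols)
        self.term_names = names

        # informative = intervals span >= 2 distinct covariate patterns (among
        # covariates actually in the design) and the patient has >= 1 event
        pattern = cat.astype(np.int64)
        if self.adjust_age:
            pattern = pattern * 512 + band
        if self.adjust_season:
            pattern = pattern * 8 + season
        n_groups = len(self._group_starts)
        informative = np.zeros(n_groups, dtype=bool)
        group_events = np.add.reduceat(self._n, self._group_starts)
        for gi, s in enumerate(self._group_starts):
            e = (
                self._group_starts[gi + 1]
                if gi + 1 < n_groups
                else len(pattern)
            )
            informative[gi] = group_events[gi] > 0 and len(np.unique(pattern[s:e])) > 1
        keep_rows = informative[self._group_ids]
        self.n_cases_total = int((group_events > 0).sum())
        self.n_cases_used = int(informative.sum())
        self.n_dropped_noninformative = self.n_cases_total - self.n_cases_used
        if self.n_cases_used == 0:
            raise EstimationError(
                "no informative patients: every case's intervals share a single "
                "covariate pattern"
            )
        self._X = self._X[keep_rows]
        self._t = self._t[keep_rows]
        self._n = self._n[keep_rows]
        gkept = self._group_ids[keep_rows]
        _, gkept = np.unique(gkept, return_inverse=True)
        self._group_starts = np.concatenate(([0], np.flatnonzero(np.diff(gkept)) + 1))
        self._group_events = np.add.reduceat(self._n, self._group_starts)
        self._log_t = np.log(self._t)

    # -- likelihood --------------------------------------------------------

    def loglik_grad_hess(self, coef: np.ndarray):
        """Exact conditional log-likelihood with analytic derivatives."""
        coef = np.asarray(coef, dtype=np.float64)
        X, t, n = self._X, self._t, self._n
        gs = self._group_starts
        eta = X @ coef + self._log_t
        gmax = np.maximum.reduceat(eta, gs)
        z = np.exp(eta - gmax[self._grp()])
        denom = np.add.reduceat(z, gs)
        if not np.all(np.isfinite(denom)) or np.any(denom <= 0):
            bad = self._pid[np.flatnonzero(~np.isfinite(denom) | (denom <= 0))[:1]]
            raise FloatingPointError(f"non-finite likelihood (patient {bad})")
        log_denom = np.log(denom) + gmax
        ll = float(np.sum(n * (eta - log_denom[self._grp()])))
        w = z / denom[self._grp()]  # within-patient multinomial probabilities
        resid = n - self._group_events[self._grp()] * w
        grad = X.T @ resid
        Nw = self._group_events[self._grp()] * w
        Xw = X * Nw[:, None]
        M = np.add.reduceat(Xw, gs, axis=0)  # per-patient sum of N·w·x
        hess = -(X.T @ Xw) + (M.T * (1.0 / self._group_events)) @ M
        return ll, grad, hess

    def _grp(self) -> np.ndarray:
        if not hasattr(self, "_grp_cache") or len(self._grp_cache) != len(self._t):
            n_groups = len(self._group_starts)
            grp = np.zeros(len(self._t), dtype=np.int64)
            grp[self._group_starts[1:]] = 1
            self._grp_cache = np.cumsum(grp)
        return self._grp_cache

    # -- fitting -----------------------------------------------------------

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> "SCCSResults":
        k = self._X.shape[1]
        beta = np.zeros(k)
        ll, grad, hess = self.loglik_grad_hess(beta)
        iterations = 0
        converged = bool(np.max(np.abs(grad)) < tol)
        while not converged and iterations < maxiter:
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
            # step-halving safeguard
            new = None
            for _ in range(40):
                try:
                    new = self.loglik_grad_hess(beta + step)
                except FloatingPointError:
                    new = None
                if new is not None and new[0] >= ll - 1e-12:
                    break
                step = step / 2.0
                new = None
            if new is None:
                break
            beta = beta + step
            ll, grad, hess = new
            iterations += 1
            converged = bool(np.max(np.abs(grad)) < tol)
        neg_hess = -hess
        try:
            cov = np.linalg.inv(neg_hess)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"singular information matrix: {exc}") from exc
        warnings = []
        if not converged:
            warnings.append("Newton iterations did not converge")
        sep = [self.term_names[i] for i in range(k) if abs(beta[i]) > 10]
        if sep:
            warnings.append(
                f"possible separation: |log IRR| > 10 for {', '.join(sep)}"
            )
        return SCCSResults(
            model=self,
            params=pd.Series(beta, index=self.term_names),
            cov=pd.DataFrame(cov, index=self.term_names, columns=self.term_names),
            loglik=ll,
            converged=converged,
            iterations=iterations,
            n_cases_used=self.n_cases_used,
            n_dropped_noninformative=self.n_dropped_noninformative,
            warnings=warnings,
        )


@dataclass
class SCCSResults:
    """Fitted SCCS conditional Poisson model."""

    model: SCCSModel
    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    converged: bool
    iterations: int
    n_cases_used: int
    n_dropped_noninformative: int
    warnings: list = field(default_factory=list)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def cov_params(self) -> pd.DataFrame:
        return self.cov

    def wald(self, term: str, level: float = 0.95) -> IrrEstimate:
        """IRR, Wald confidence interval and two-sided p-value for one term."""
        if term not in self.params.index:
            raise KeyError(f"term {term!r} not in model (have {list(self.params.index)})")
        coef = float(self.params[term])
        se = float(self.bse[term])
        z = stats.norm.ppf(1 - (1 - level) / 2)
        p = 2 * stats.norm.sf(abs(coef) / se) if se > 0 else (1.0 if coef == 0 else 0.0)
        return IrrEstimate(
            term=term,
            irr=float(np.exp(coef)),
            ci_low=float(np.exp(coef - z * se)),
            ci_high=float(np.exp(coef + z * se)),
            p_value=float(p),
        )

    def contrast(self, term_a: str, term_b: str, level: float = 0.95) -> IrrEstimate:
        """Exponentiated difference of two coefficients (IRR of a versus b)."""
        for term in (term_a, term_b):
            if term not in self.params.index:
                raise KeyError(f"term {term!r} not in model")
        diff = float(self.params[term_a] - self.params[term_b])
        var = float(
            self.cov.loc[term_a, term_a]
            + self.cov.loc[term_b, term_b]
            - 2 * self.cov.loc[term_a, term_b]
        )
        se = np.sqrt(max(var, 0.0))
        z = stats.norm.ppf(1 - (1 - level) / 2)
        p = 2 * stats.norm.sf(abs(diff) / se) if se > 0 else (1.0 if diff == 0 else 0.0)
        return IrrEstimate(
            term=f"{term_a} vs {term_b}",
            irr=float(np.exp(diff)),
            ci_low=float(np.exp(diff - z * se)),
            ci_high=float(np.exp(diff + z * se)),
            p_value=float(p),
        )

    def irr_frame(self, level: float = 0.95) -> pd.DataFrame:
        rows = [self.wald(t, level) for t in self.params.index]
        return pd.DataFrame(
            {
                "term": [r.term for r in rows],
                "irr": [r.irr for r in rows],
                "ci_low": [r.ci_low for r in rows],
                "ci_high": [r.ci_high for r in rows],
                "p_value": [r.p_value for r in rows],
            }
        )

    def summary(self) -> str:
        lines = [
            "SCCS conditional Poisson regression",
            f"  cases used: {self.n_cases_used}"
            f"  (non-informative dropped: {self.n_dropped_noninformative})",
            f"  log-likelihood: {self.loglik:.4f}"
            f"   converged: {self.converged} in {self.iterations} iteration(s)",
            "",
            f"  {'term':<14} {'IRR':>8} {'95% CI':>16} {'P-value':>8}",
        ]
        for term in self.params.index:
            est = self.wald(term)
            lines.append(
                f"  {term:<14} {est.irr:>8.2f} "
                f"{est.ci_low:>7.2f}–{est.ci_high:<8.2f} {est.format_p():>8}"
            )
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "cov": self.cov.to_numpy().tolist(),
            "terms": list(self.params.index),
            "loglik": self.loglik,
            "converged": self.converged,
            "iterations": self.iterations,
            "n_cases_used": self.n_cases_used,
            "n_dropped_noninformative": self.n_dropped_noninformative,
            "warnings": list(self.warnings),
        }
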