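"""AIC/BIC model comparison and the best-model decision rule.

The comparison table mirrors the study layout: one row per fitted model with
null and fitted log-likelihoods, the free-parameter count ``k``, and
``AIC = -2 ll + 2 k`` and ``BIC = -2 ll + k ln(N)``.  ``N`` is an explicit,
logged setting (default: number of analysis records) because the BIC is not
invariant to how "observations" are counted in clustered data.

Model choice: the minimum-BIC row wins among rows passing the spline
significance screen (flexible-model rows whose every spline slope is
significant at the 5% level; rows without spline terms always pass).  AIC
near-ties among flexible fits are recorded in the rationale, reflecting the
practice of preferring the simplest spline model when AICs differ
negligibly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_AIC_NEAR_TIE = 0.001  # relative AIC difference treated as negligible (0.1%)


def aic(ll: float, k: int) -> float:
    """Akaike information criterion, -2*ll + 2k."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return -2.0 * ll + 2.0 * k


def bic(ll: float, k: int, n: int) -> float:
    """Bayesian information criterion, -2*ll + k*ln(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return -2.0 * ll + k * np.log(n)


@dataclass(frozen=True)
class ComparisonRow:
    frailty: bool
    group: str            # "Cox" | "Parametric" | "Flexible Model"
    model_label: str      # e.g. "Weibull", "df = 2"
    ll_null: float
    ll_model: float
    k: int
    aic: float
    bic: float
    spline_pvalues: tuple[float, ...] = ()
    df: int | None = None

    def passes_screen(self, alpha: float = 0.05) -> bool:
        return all(p < alpha for p in self.spline_pvalues)


def make_row(fit, frailty: bool, group: str, model_label: str, n: int) -> ComparisonRow:
    """Build one comparison row from any fit object.

    The fit must expose ``loglik``, ``loglik_null`` and ``n_parameters``
    (``CoxFit`` parameter count is its coefficient count plus one for a
    profiled frailty variance).
    """
    if hasattr(fit, "n_parameters"):
        k = fit.n_parameters
    else:  # CoxFit
        k = int(np.sum(np.abs(fit.beta) >= 0)) + (1 if fit.theta > 0 else 0)
    ll = fit.loglik
    ll0 = fit.loglik_null
    pv = ()
    dfv = None
    if hasattr(fit, "spline_pvalues") and hasattr(fit, "df"):
        dfv = fit.df
        if fit.df >= 1 and np.isfinite(fit.covariance).all():
            pv = tuple(fit.spline_pvalues)
    return ComparisonRow(
        frailty=frailty, group=group, model_label=model_label,
        ll_null=float(ll0), ll_model=float(ll), k=int(k),
        aic=aic(ll, k), bic=bic(ll, k, n),
        spline_pvalues=pv, df=dfv,
    )


def compare(entries, n: int) -> list[ComparisonRow]:
    """Rows for a list of ``(fit, frailty, group, model_label)`` entries.

    Rows are ordered frailty-free first, then by group (Cox, Parametric,
    Flexible Model), matching the comparison-table layout.
    """
    if len(entries) < 2:
        raise ValueError("need at least two fits to compare")
    rows = [make_row(f, fr, g, lab, n) for f, fr, g, lab in entries]
    group_order = {"Cox": 0, "Parametric": 1, "Flexible Model": 2}
    rows.sort(key=lambda r: (r.frailty, group_order.get(r.group, 99)))
    return rows


def comparison_table(rows) -> pd.DataFrame:
    """Comparison rows as a DataFrame with the standard column names."""
    return pd.DataFrame(
        {
            "Frailty": ["Yes" if r.frailty else "None" for r in rows],
            "Model": [r.group for r in rows],
            "Model_": [r.model_label for r in rows],
            "ll(null)": [round(r.ll_null, 2) for r in rows],
            "ll(model)": [round(r.ll_model, 2) for r in rows],
            "df": [r.k for r in rows],
            "AIC": [round(r.aic, 2) for r in rows],
            "BIC": [round(r.bic, 2) for r in rows],
        }
    )


@dataclass
class SelectionDecision:
    chosen_row: ComparisonRow
    rationale: list[str] = field(default_factory=list)


def select_best(rows, alpha: float = 0.05,
                aic_near_tie: float = DEFAULT_AIC_NEAR_TIE) -> SelectionDecision:
    """Minimum-BIC model among rows passing the spline significance screen.

    Flexible-model rows with any non-significant spline slope (Wald p >=
    ``alpha``) are screened out, unless that would remove every candidate.
    The rationale records BIC ranking, the screen, and AIC near-ties among
    flexible fits (relative difference below ``aic_near_tie``).
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no rows to select from")
    rationale = []

    eligible = [r for r in rows if r.passes_screen(alpha)]
    screened = [r for r in rows if not r.passes_screen(alpha)]
    if screened:
        rationale.append(
            "screened out (non-significant spline slope at "
            f"alpha={alpha}): " + ", ".join(r.model_label for r in screened)
        )
    if not eligible:
        eligible = rows
        rationale.append("no row passed the significance screen; screen waived")

    chosen = min(eligible, key=lambda r: r.bic)
    rationale.append(
        f"minimum BIC {chosen.bic:.2f} at "
        f"{chosen.group} {chosen.model_label} (frailty={chosen.frailty})"
    )

    rp_rows = [r for r in eligible if r.df is not None and r.frailty == chosen.frailty]
    if len(rp_rows) >= 2:
        best_aic = min(r.aic for r in rp_rows)
        ties = [r for r in rp_rows
                if abs(r.aic - best_aic) <= aic_near_tie * abs(best_aic)]
        if len(ties) >= 2:
            simplest = min(ties, key=lambda r: r.df)
            rationale.append(
                "AIC near-tie (<"
                f"{100 * aic_near_tie:.2g}%) among flexible df="
                f"{sorted(r.df for r in ties)}; simplest is df={simplest.df}"
            )
    return SelectionDecision(chosen_row=chosen, rationale=rationale)
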