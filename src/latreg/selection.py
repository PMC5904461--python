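"""Multimodel inference: backward stepwise selection, all-subsets tables
and relative variable importance across wavelet scales.

Model comparison uses QIC for GEEs and AIC (optionally AICc) for
wavelet-revised / multiresolution models.  Backward selection always
respects the hierarchy of terms: a main effect is never removed while an
interaction or polynomial containing it remains in the model.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formula import Formula
from .glm import ModelFit
from .grid import PadSpec
from .wavelets import WaveletSpec
from .wrm import fit_wrm, scale_wmrr

MAX_MMI_TERMS = 12


@dataclass
class ModelTable:
    """All-subsets model-selection table with Akaike weights."""

    table: pd.DataFrame  # columns: terms, k, criterion, delta, weight
    criterion_name: str

    def weight_of(self, variable: str) -> float:
        """Summed weight of models containing the variable (RVI)."""
        has = self.table["terms"].map(lambda ts: variable in ts)
        return float(self.table.loc[has, "weight"].sum())


def _refit(fit: ModelFit, data, formula: Formula,
           scale=None, detail=None) -> ModelFit:
    """Refit the same model class on a new formula."""
    m = fit.meta
    if fit.kind == "gee":
        from .gee import fit_gee

        return fit_gee(
            data, formula, fit.family, corstr=m["corstr"],
            cluster=m["cluster"], scale_fix=m["scale_fix"],
            moran=m.get("moran"),
        )
    if fit.kind == "wmrr" or scale is not None:
        return scale_wmrr(
            data, formula, fit.family,
            scale=scale if scale is not None else m["scale"],
            detail=detail if detail is not None else m.get("detail", True),
            spec=m["spec"], pad=m["pad"], scale_fix=m["scale_fix"],
        )
    if fit.kind == "wrm":
        return fit_wrm(
            data, formula, fit.family, level=m["level"], spec=m["spec"],
            pad=m["pad"], scale_fix=m["scale_fix"], moran=None,
        )
    from .glm import fit_glm

    return fit_glm(data, formula, fit.family)


def _criterion_name(fit: ModelFit, use_aicc: bool) -> str:
    if fit.kind == "gee":
        return "qic"
    return "aicc" if use_aicc else "aic"


def step_backward(fit: ModelFit, data, use_aicc: bool = False,
               trace: bool = False) -> dict:
    """Backward stepwise selection from a full GEE or WRM fit.

    At each step every hierarchy-respecting single-term deletion is
    evaluated; the one with the lowest criterion is taken if it improves on
    the current model (ties among deletions are broken by term order).
    Returns the reduced formula and the per-step log.
    """
    if not fit.converged:
        warnings.warn("starting model did not converge; stepping anyway")
    crit_name = _criterion_name(fit, use_aicc)
    current = fit
    formula = fit.formula
    log_rows = [{
        "step": 0, "removed": None, "criterion": current.criterion(use_aicc),
        "model": str(formula),
    }]
    step = 0
    while formula.terms:
        candidates = formula.removable()
        if not candidates:
            break
        best = None
        for term in sorted(candidates, key=lambda t: t.label):
            trial_formula = formula.drop(term)
            trial = _refit(current, data, trial_formula)
            c = trial.criterion(use_aicc)
            if best is None or c < best[0]:
                best = (c, term, trial)
        if best is None or best[0] >= current.criterion(use_aicc):
            break
        step += 1
        c, term, trial = best
        formula = formula.drop(term)
        current = trial
        log_rows.append({
            "step": step, "removed": term.label, "criterion": c,
            "model": str(formula),
        })
        if trace:
            print(f"step {step}: removed {term.label}  {crit_name}={c:.4f}")
    return {
        "model": formula,
        "fit": current,
        "table": pd.DataFrame(log_rows),
        "criterion_name": crit_name,
    }


def mmi(fit: ModelFit, data, scale: int | None = None,
        detail: bool | None = None, use_aicc: bool = False,
        trace: bool = False) -> ModelTable:
    """All-subsets multimodel inference table for a GEE/WRM/WMRR fit.

    Fits every subset of the fitted terms (the intercept is always kept),
    scores each with the appropriate criterion and returns the table sorted
    ascending with deltas and Akaike weights.  Subset fits that fail are
    flagged and excluded from the weight normalisation.
    """
    terms = list(fit.formula.terms)
    p = len(terms)
    if p > MAX_MMI_TERMS:
        raise ValueError(
            f"{p} candidate terms would enumerate 2^{p} models; "
            f"limit is {MAX_MMI_TERMS}"
        )
    crit_name = _criterion_name(fit, use_aicc)
    rows = []
    for size in range(p + 1):
        for subset in itertools.combinations(terms, size):
            trial_formula = fit.formula.with_terms(subset)
            try:
                trial = _refit(fit, data, trial_formula, scale=scale,
                               detail=detail)
                crit = trial.criterion(use_aicc)
                ok = True
            except Exception as e:  # noqa: BLE001 - flagged, not fatal
                warnings.warn(
                    f"subset {trial_formula} failed to fit: {e}"
                )
                crit, ok = np.nan, False
            rows.append({
                "terms": tuple(t.label for t in subset),
                "k": len(subset) + (1 if fit.formula.intercept else 0),
                "criterion": crit,
                "ok": ok,
            })
            if trace and ok:
                print(f"{rows[-1]['terms']}: {crit_name}={crit:.4f}")
    tab = pd.DataFrame(rows)
    good = tab["ok"]
    best = tab.loc[good, "criterion"].min()
    tab["delta"] = tab["criterion"] - best
    w = np.exp(-0.5 * tab.loc[good, "delta"])
    tab.loc[good, "weight"] = w / w.sum()
    tab.loc[~good, "weight"] = np.nan
    # sort: criterion, then fewer terms, then lexical labels (stable ties)
    tab["_nt"] = tab["terms"].map(len)
    tab["_lex"] = tab["terms"].map(lambda ts: ",".join(ts))
    tab = (
        tab.sort_values(["criterion", "_nt", "_lex"], na_position="last")
        .drop(columns=["_nt", "_lex"])
        .reset_index(drop=True)
    )
    return ModelTable(table=tab, criterion_name=crit_name)


def rvi(formula, family, data, maxlevel: int, detail: bool = True,
        spec: WaveletSpec = WaveletSpec(), pad: PadSpec = PadSpec(),
        use_aicc: bool = False, trace: bool = False):
    """Relative variable importance as a function of wavelet scale.

    For each scale 1..maxlevel an all-subsets table is built from
    scale-specific multiresolution fits; RVI(variable, scale) is the summed
    Akaike weight of the models containing that variable.  Returns the
    (variable x scale) matrix and the underlying tables.
    """
    if maxlevel < 1:
        raise ValueError("maxlevel must be >= 1")
    from .formula import parse_formula

    if isinstance(formula, str):
        formula = parse_formula(formula)
    variables = [t.label for t in formula.terms]
    importance = pd.DataFrame(
        index=variables, columns=range(1, maxlevel + 1), dtype=float
    )
    tables: dict[int, ModelTable] = {}
    for s in range(1, maxlevel + 1):
        full = scale_wmrr(data, formula, family, scale=s, detail=detail,
                          spec=spec, pad=pad)
        table = mmi(full, data, scale=s, detail=detail, use_aicc=use_aicc)
        tables[s] = table
        for v in variables:
            importance.loc[v, s] = table.weight_of(v)
        if trace:
            print(f"-- scale {s} --")
            print(table.table.to_string(index=False))
    return importance, tables
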