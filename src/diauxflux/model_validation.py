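"""Flux-sum based validation of competing metabolic model variants.

The flux-sum of metabolite i under flux vector v is

    Phi_i = 0.5 * sum_j |S_ij v_j|

which at steady state equals the metabolite's turnover (total production
= total consumption).  Replicate flux simulations of two model variants
are compared per reaction with two-sided Wilcoxon signed-rank tests and
per replicate-pair Spearman correlations (to separate flux rerouting
from uniform scaling), and flux-sum changes are scored as predictors of
observed metabolite accumulation using balanced accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fba_engine import RegulatoryRuleSet, StoichiometricModel, replicate_fluxes


# ---------------------------------------------------------------------------
# Flux-sum


def flux_sum(S: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Phi_i = 0.5 * sum_j |S_ij v_j| per metabolite.

    Accepts a single flux vector (returns a vector over metabolites) or
    a reactions x replicates matrix (returns metabolites x replicates).
    """
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("flux vector contains non-finite entries")
    if v.ndim == 1:
        return 0.5 * np.abs(S * v[None, :]).sum(axis=1)
    return 0.5 * np.abs(S[:, :, None] * v[None, :, :]).sum(axis=1)


def flux_sum_profile(model: StoichiometricModel, fluxes: pd.DataFrame,
                     model_label: str = "") -> "FluxSumProfile":
    """Flux-sum matrix (metabolites x replicates) from a flux matrix."""
    S = model.S
    V = fluxes.loc[model.reaction_ids].to_numpy()
    phi = 0.5 * np.abs(S[:, :, None] * V[None, :, :]).sum(axis=1)
    return FluxSumProfile(
        phi=pd.DataFrame(phi, index=model.metabolite_ids, columns=fluxes.columns),
        model_label=model_label,
    )


@dataclass
class FluxSumProfile:
    phi: pd.DataFrame  # metabolites x replicates
    model_label: str = ""


# ---------------------------------------------------------------------------
# Flux comparison statistics


def paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p for one paired sample.

    Zero differences are dropped (Wilcoxon convention); an all-zero
    difference vector gives p = 1.  The exact null distribution is used
    for n <= 25 (no ties assumed by scipy's exact mode; falls back to
    the normal approximation when ties are present).
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    method = "exact" if len(d) <= 25 and len(np.unique(np.abs(d))) == len(d) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         method=method)
    return float(res.pvalue)


def compare_model_fluxes(fluxes_a: pd.DataFrame, fluxes_b: pd.DataFrame,
                         alpha: float = 0.1) -> tuple[pd.Series, float]:
    """Per-reaction paired Wilcoxon p-values and the fraction significant.

    Replicates are paired by column position.  Reactions with identical
    fluxes in every replicate count as not changed (p = 1).
    """
    if fluxes_a.shape != fluxes_b.shape:
        raise ValueError("flux matrices must have identical shapes")
    common = fluxes_a.index
    pvals = pd.Series(
        [paired_wilcoxon(fluxes_a.loc[r].to_numpy(), fluxes_b.loc[r].to_numpy())
         for r in common],
        index=common, name="p_wilcoxon",
    )
    fraction = float((pvals < alpha).mean())
    return pvals, fraction


def spearman_rerouting(fluxes_a: pd.DataFrame, fluxes_b: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation over reactions for every cross-model replicate pair.

    Returns a long table (rep_a, rep_b, rho); pairs where either flux
    vector is constant (rank correlation undefined) are excluded with a
    warning.  A median near 1 means the variants only rescale fluxes, a
    low median means genuine rerouting.
    """
    if fluxes_a.shape[1] < 2 or fluxes_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates in each flux matrix")
    rows = []
    skipped = 0
    for ca in fluxes_a.columns:
        va = fluxes_a[ca].to_numpy()
        for cb in fluxes_b.columns:
            vb = fluxes_b[cb].to_numpy()
            if np.ptp(va) == 0 or np.ptp(vb) == 0:
                skipped += 1
                continue
            rho = stats.spearmanr(va, vb).statistic
            rows.append((ca, cb, float(rho)))
    if skipped:
        import warnings
        warnings.warn(f"{skipped} replicate pairs had constant fluxes; excluded")
    return pd.DataFrame(rows, columns=["rep_a", "rep_b", "rho"])


# ---------------------------------------------------------------------------
# Balanced accuracy


@dataclass
class ValidationReport:
    """Per-metabolite confusion counts and balanced accuracy.

    ``table`` columns: TP, FP, TN, FN, sensitivity, specificity,
    balanced_accuracy.  A class with zero members contributes rate 0
    (so all-negative truth with all-negative predictions scores 0.5,
    and a variant with no correct matches can score exactly 0).
    """

    table: pd.DataFrame
    comparisons: list = field(default_factory=list)
    model_label: str = ""
    predicted: pd.DataFrame | None = None
    observed: pd.DataFrame | None = None


def balanced_accuracy_eval(predicted: pd.DataFrame, observed: pd.DataFrame,
                           model_label: str = "") -> ValidationReport:
    """Score boolean predictions against boolean observations.

    Both inputs are metabolite x comparison boolean frames with matching
    shape and labels; comparisons are pooled per metabolite.
    """
    if predicted.shape != observed.shape or list(predicted.columns) != list(observed.columns):
        raise ValueError("predicted and observed must have matching shape and columns")
    if predicted.shape[1] == 0:
        raise ValueError("empty comparison set")
    P = predicted.to_numpy(dtype=bool)
    O = observed.to_numpy(dtype=bool)
    tp = (P & O).sum(axis=1)
    fp = (P & ~O).sum(axis=1)
    tn = (~P & ~O).sum(axis=1)
    fn = (~P & O).sum(axis=1)
    with np.errstate(invalid="ignore"):
        sens = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        spec = np.where(tn + fp > 0, tn / np.maximum(tn + fp, 1), 0.0)
    bal = (sens + spec) / 2.0
    table = pd.DataFrame({
        "TP": tp, "FP": fp, "TN": tn, "FN": fn,
        "sensitivity": sens, "specificity": spec, "balanced_accuracy": bal,
    }, index=predicted.index)
    return ValidationReport(table=table, comparisons=list(predicted.columns),
                            model_label=model_label,
                            predicted=predicted.astype(bool),
                            observed=observed.astype(bool))


# ---------------------------------------------------------------------------
# End-to-end validation


def predict_flux_sum_changes(
    model: StoichiometricModel,
    rules: RegulatoryRuleSet,
    knockouts: list[str],
    phases: tuple[str, ...] = ("pre", "post"),
    metabolites: list[str] | None = None,
    alpha: float = 0.1,
    n_replicates: int = 13,
    jitter_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Boolean metabolite x comparison matrix of predicted flux-sum changes.

    For each (knockout, phase) the knockout and wild-type replicate
    simulations share jitter (same seed), and a metabolite is predicted
    changed iff the paired Wilcoxon test on its flux-sum replicates gives
    p < alpha.  This is the prediction arm of the validation; it is
    exposed separately so closed-loop experiments can plant observations
    from exactly the same seeded decision rule.
    """
    mets = metabolites or model.metabolite_ids
    comparisons = [(ko, ph) for ko in knockouts for ph in phases]
    predicted = pd.DataFrame(False, index=mets,
                             columns=[f"{ko}:{ph}" for ko, ph in comparisons])
    for i, (ko, ph) in enumerate(comparisons):
        rep_seed = (seed + 7919 * i) % (2**31)
        wt = replicate_fluxes(model, rules, None, ph, n_replicates,
                              jitter_fraction, seed=rep_seed)
        mut = replicate_fluxes(model, rules, ko, ph, n_replicates,
                               jitter_fraction, seed=rep_seed)
        phi_wt = flux_sum_profile(model, wt).phi
        phi_mut = flux_sum_profile(model, mut).phi
        for met in mets:
            p = paired_wilcoxon(phi_mut.loc[met].to_numpy(),
                                phi_wt.loc[met].to_numpy())
            predicted.loc[met, f"{ko}:{ph}"] = p < alpha
    return predicted


def end_to_end_validation(
    model: StoichiometricModel,
    rule_sets: dict,
    knockouts: list[str],
    diff_results: dict,
    metabolite_map: dict,
    alpha: float = 0.1,
    phases: tuple[str, ...] = ("pre", "post"),
    n_replicates: int = 13,
    jitter_fraction: float = 0.05,
    seed: int = 0,
) -> dict:
    """Score each model variant's flux-sum predictions against data.

    For every (knockout strain, phase) comparison and each variant in
    ``rule_sets`` (label -> RegulatoryRuleSet): the prediction is
    positive iff the paired Wilcoxon test on knockout-vs-wild-type
    flux-sum replicates gives p < alpha; the observation is positive iff
    the linear model for that strain/phase (``diff_results[(strain,
    phase)]``, a DiffResult) gives p < alpha for the mapped feature.
    ``metabolite_map`` maps model metabolite ids to measured feature
    ids; unmapped metabolites are skipped.  Replicate jitter is seeded
    identically for knockout and wild type so unaffected metabolites
    have exactly zero paired differences.

    Returns {model_label: ValidationReport}.
    """
    mets = [m for m in metabolite_map if m in model.metabolite_ids]
    if not mets:
        raise ValueError("metabolite_map matches no model metabolites")
    comparisons = [(ko, ph) for ko in knockouts for ph in phases]
    if not comparisons:
        raise ValueError("empty comparison set")

    observed = pd.DataFrame(False, index=mets,
                            columns=[f"{ko}:{ph}" for ko, ph in comparisons])
    for ko, ph in comparisons:
        diff = diff_results[(ko, ph)]
        for met in mets:
            fid = metabolite_map[met]
            if fid in diff.table.index:
                observed.loc[met, f"{ko}:{ph}"] = bool(
                    diff.table.loc[fid, "p_raw"] < alpha)

    reports = {}
    for label, rules in rule_sets.items():
        predicted = predict_flux_sum_changes(
            model, rules, knockouts, phases, mets, alpha,
            n_replicates, jitter_fraction, seed)
        reports[label] = balanced_accuracy_eval(predicted, observed, label)
    return reports
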