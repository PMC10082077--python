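"""Phase- and knockout-constrained flux balance analysis.

Solves FBA with a pFBA-style (minimum total flux) secondary objective for
deterministic flux vectors, steps a static-optimization dynamic FBA (dFBA)
simulation across the diauxic shift, and ranks single-gene deletion strains
by the discrepancy in post-shift growth between two regulatory model
variants.

A :class:`RegulatoryRuleSet` augments the structural gene-protein-reaction
(GPR) associations of a stoichiometric model with phase-specific regulatory
requirements: a rule ``(gene, phase, reaction, action)`` states that the
regulator gene is required in that growth phase for the reaction to operate
normally, so the action (``disable`` or ``scale_bound``) is applied to the
reaction's bounds when the gene is deleted.  Structural knockouts are
handled by ordinary boolean GPR evaluation.
"""

from __future__ import annotations

import io
from contextlib import redirect_stderr
from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd
from cobra.flux_analysis import pfba
from cobra.util.array import create_stoichiometric_matrix

PHASES = ("pre", "post")
RULE_ACTIONS = ("disable", "scale_bound")

#: |S v| tolerance for calling a returned solution mass balanced
FEASIBILITY_TOL = 1e-9


@dataclass
class StoichiometricModel:
    """A stoichiometric metabolic model plus study-specific annotations.

    Wraps a :class:`cobra.Model` (which owns metabolites, reactions,
    bounds, GPR strings and the biomass objective) together with the list
    of regulatory genes that appear only in rule sets, and per-phase
    exchange media describing nutrient availability before and after the
    diauxic shift.
    """

    cobra_model: cobra.Model
    biomass_id: str
    regulator_genes: tuple[str, ...] = ()
    #: phase -> {exchange reaction id: (lb, ub)}
    phase_media: dict = field(default_factory=dict)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.cobra_model.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.cobra_model.metabolites]

    @property
    def structural_genes(self) -> list[str]:
        return [g.id for g in self.cobra_model.genes]

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.structural_genes) | set(self.regulator_genes))

    @property
    def S(self) -> np.ndarray:
        """Dense stoichiometric matrix, metabolites x reactions."""
        return create_stoichiometric_matrix(self.cobra_model)

    def validate(self) -> None:
        m = self.cobra_model
        if self.biomass_id not in {r.id for r in m.reactions}:
            raise ValueError(f"objective reaction {self.biomass_id!r} not in model")
        for r in m.reactions:
            if r.lower_bound > r.upper_bound:
                raise ValueError(f"reaction {r.id}: lower bound exceeds upper bound")
        for phase, medium in self.phase_media.items():
            if phase not in PHASES:
                raise ValueError(f"unknown phase {phase!r}")
            for rid in medium:
                if rid not in {r.id for r in m.reactions}:
                    raise ValueError(f"medium reaction {rid!r} not in model")


@dataclass(frozen=True)
class RegulatoryRule:
    """One phase-specific regulatory requirement.

    ``factor`` is only meaningful for ``scale_bound`` and multiplies both
    bounds of the target reaction when the regulator is deleted.
    """

    gene: str
    phase: str
    reaction: str
    action: str
    factor: float = 0.5

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.action not in RULE_ACTIONS:
            raise ValueError(f"action must be one of {RULE_ACTIONS}, got {self.action!r}")


@dataclass
class RegulatoryRuleSet:
    model_label: str
    rules: tuple[RegulatoryRule, ...] = ()

    def validate_for(self, model: StoichiometricModel) -> None:
        rxn_ids = set(model.reaction_ids)
        gene_ids = set(model.genes)
        for rule in self.rules:
            if rule.reaction not in rxn_ids:
                raise ValueError(
                    f"{self.model_label}: rule targets unknown reaction {rule.reaction!r}"
                )
            if rule.gene not in gene_ids:
                raise ValueError(
                    f"{self.model_label}: rule references unknown gene {rule.gene!r}"
                )

    def genes(self) -> set[str]:
        return {r.gene for r in self.rules}


@dataclass
class FluxSolution:
    """Result of one FBA solve; ``fluxes`` indexed by reaction id."""

    fluxes: pd.Series
    objective_value: float
    status: str  # "optimal" | "infeasible"


@dataclass
class DFBATrajectory:
    time: np.ndarray          # h
    biomass: np.ndarray       # gDW/L
    glucose: np.ndarray       # mmol/L
    ethanol: np.ndarray       # mmol/L
    growth_rate: np.ndarray   # 1/h, instantaneous
    shift_time: float | None  # h, glucose-depletion phase flip
    pre_rate: float           # 1/h, biomass-weighted mean growth, pre phase
    post_rate: float | None   # 1/h, or None if the shift never happened


# ---------------------------------------------------------------------------
# FBA


def _apply_regulation(m: cobra.Model, rule_set: RegulatoryRuleSet | None,
                      knockout_gene: str | None, phase: str) -> None:
    """Apply GPR knockout plus phase-matched regulatory rules in-place."""
    if knockout_gene is not None and knockout_gene in {g.id for g in m.genes}:
        m.genes.get_by_id(knockout_gene).knock_out()
    if rule_set is None or knockout_gene is None:
        return
    for rule in rule_set.rules:
        if rule.gene != knockout_gene or rule.phase != phase:
            continue
        rxn = m.reactions.get_by_id(rule.reaction)
        if rule.action == "disable":
            rxn.bounds = (0.0, 0.0)
        else:  # scale_bound
            lb, ub = rxn.bounds
            rxn.bounds = (lb * rule.factor, ub * rule.factor)


def solve_fba(
    model: StoichiometricModel,
    rule_set: RegulatoryRuleSet | None = None,
    knockout_gene: str | None = None,
    phase: str = "pre",
    exchange_bounds: dict | None = None,
) -> FluxSolution:
    """Maximize biomass under knockout + regulatory constraints.

    Among alternate optima the minimum-total-|flux| (pFBA) solution is
    returned so downstream replicate statistics see deterministic fluxes.
    ``exchange_bounds`` overrides reaction bounds (used by dFBA and by the
    per-phase media); entries are ``{reaction_id: (lb, ub)}``.

    An infeasible LP, or one whose optimum is not finite, is reported with
    ``status="infeasible"`` and objective 0 by convention.
    """
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}, got {phase!r}")
    if knockout_gene is not None and knockout_gene not in model.genes:
        raise ValueError(f"knockout gene {knockout_gene!r} not in model gene list")
    m = model.cobra_model
    with m:
        m.objective = model.biomass_id
        medium = model.phase_media.get(phase, {})
        for rid, bounds in medium.items():
            m.reactions.get_by_id(rid).bounds = bounds
        if exchange_bounds:
            for rid, bounds in exchange_bounds.items():
                m.reactions.get_by_id(rid).bounds = bounds
        _apply_regulation(m, rule_set, knockout_gene, phase)
        obj = m.slim_optimize(error_value=np.nan)
        if not np.isfinite(obj):
            zeros = pd.Series(0.0, index=model.reaction_ids)
            return FluxSolution(fluxes=zeros, objective_value=0.0, status="infeasible")
        # pFBA: fix the objective at its optimum, minimize total |flux|
        with redirect_stderr(io.StringIO()):  # cobra warns about zero growth
            sol = pfba(m)
        fluxes = sol.fluxes.reindex(model.reaction_ids)
    return FluxSolution(fluxes=fluxes, objective_value=float(obj), status="optimal")


# ---------------------------------------------------------------------------
# dFBA


@dataclass
class DFBAKinetics:
    """Michaelis-Menten uptake kinetics for the two-substrate simulation.

    ``ki_glucose`` implements catabolite repression: the ethanol uptake
    capacity is multiplied by ``ki/(ki + [glucose])`` so respiration of
    ethanol only switches on as glucose runs out.
    """

    vmax_glucose: float = 10.0   # mmol gDW^-1 h^-1
    km_glucose: float = 0.5      # mmol/L
    vmax_ethanol: float = 6.0
    km_ethanol: float = 0.5
    ki_glucose: float = 0.2      # mmol/L, repression constant


def run_dfba(
    model: StoichiometricModel,
    rule_set: RegulatoryRuleSet | None = None,
    knockout_gene: str | None = None,
    glucose_exchange: str = "EX_glc_e",
    ethanol_exchange: str = "EX_eth_e",
    initial_glucose: float = 20.0,
    initial_biomass: float = 0.05,
    dt: float = 0.1,
    horizon: float = 30.0,
    kinetics: DFBAKinetics | None = None,
    depletion_fraction: float = 0.01,
) -> DFBATrajectory:
    """Euler static-optimization dFBA across the diauxic shift.

    At every step the substrate uptake bounds are set from current
    concentrations via Michaelis-Menten kinetics, FBA is solved, and the
    biomass and external glucose/ethanol pools are updated.  The phase
    flips from ``pre`` to ``post`` when glucose falls below
    ``depletion_fraction`` of its initial concentration; phase-matched
    regulatory rules follow the flip.  Reported ``pre_rate``/``post_rate``
    are biomass-weighted mean growth rates per phase.
    """
    if dt <= 0 or horizon <= 0:
        raise ValueError("dt and horizon must be positive")
    if initial_glucose <= 0:
        raise ValueError("initial glucose must be positive")
    kin = kinetics or DFBAKinetics()

    n_steps = int(np.ceil(horizon / dt))
    t = np.zeros(n_steps + 1)
    X = np.zeros(n_steps + 1)
    G = np.zeros(n_steps + 1)
    E = np.zeros(n_steps + 1)
    mu = np.zeros(n_steps + 1)
    X[0], G[0] = initial_biomass, initial_glucose
    threshold = depletion_fraction * initial_glucose
    shift_time: float | None = None

    for k in range(n_steps):
        phase = "pre" if shift_time is None else "post"
        v_glc_max = kin.vmax_glucose * G[k] / (kin.km_glucose + G[k]) if G[k] > 0 else 0.0
        repress = kin.ki_glucose / (kin.ki_glucose + G[k])
        v_eth_max = (kin.vmax_ethanol * E[k] / (kin.km_ethanol + E[k])) * repress if E[k] > 0 else 0.0
        bounds = {
            glucose_exchange: (-v_glc_max, 0.0),
            ethanol_exchange: (-v_eth_max, 1000.0),
        }
        sol = solve_fba(model, rule_set, knockout_gene, phase, exchange_bounds=bounds)
        growth = sol.objective_value if sol.status == "optimal" else 0.0
        v_glc = sol.fluxes.get(glucose_exchange, 0.0)
        v_eth = sol.fluxes.get(ethanol_exchange, 0.0)

        mu[k] = growth
        X[k + 1] = X[k] * np.exp(growth * dt)
        # trapezoid-free Euler on pools; uptake fluxes are negative
        G[k + 1] = max(G[k] + v_glc * X[k] * dt, 0.0)
        E[k + 1] = max(E[k] + v_eth * X[k] * dt, 0.0)
        t[k + 1] = t[k] + dt
        if shift_time is None and G[k + 1] < threshold:
            shift_time = t[k + 1]
    mu[n_steps] = mu[n_steps - 1]

    if shift_time is None:
        pre_mask = np.ones(n_steps, dtype=bool)
        post_mask = np.zeros(n_steps, dtype=bool)
    else:
        pre_mask = t[:-1] < shift_time
        post_mask = ~pre_mask

    def _weighted_rate(mask: np.ndarray) -> float | None:
        if not mask.any():
            return None
        w = X[:-1][mask]
        return float(np.sum(mu[:-1][mask] * w) / np.sum(w))

    pre_rate = _weighted_rate(pre_mask)
    post_rate = _weighted_rate(post_mask)
    return DFBATrajectory(
        time=t, biomass=X, glucose=G, ethanol=E, growth_rate=mu,
        shift_time=shift_time,
        pre_rate=0.0 if pre_rate is None else pre_rate,
        post_rate=post_rate,
    )


# ---------------------------------------------------------------------------
# Strain ranking


def phase_growth(
    model: StoichiometricModel,
    rule_set: RegulatoryRuleSet | None,
    knockout_gene: str | None,
    phase: str,
) -> float:
    """Optimal growth rate under the model's static medium for a phase."""
    sol = solve_fba(model, rule_set, knockout_gene, phase)
    return sol.objective_value


def rank_strains(
    model: StoichiometricModel,
    rules_a: RegulatoryRuleSet,
    rules_b: RegulatoryRuleSet,
    genes: list[str],
    top_k: int | None = None,
    method: str = "static",
    dfba_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Rank deletion strains by |post-shift growth(B) - post-shift growth(A)|.

    Non-viable strains -- zero growth under both rule variants in both
    phases -- are excluded.  Ties break deterministically by gene id.
    ``method="static"`` evaluates post-shift growth with the model's
    ``post`` medium; ``method="dfba"`` runs the full dynamic simulation
    and uses its ``post_rate``.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    rules_a.validate_for(model)
    rules_b.validate_for(model)
    if method not in ("static", "dfba"):
        raise ValueError(f"unknown method {method!r}")

    def _post_growth(rules: RegulatoryRuleSet, gene: str) -> float:
        if method == "static":
            return phase_growth(model, rules, gene, "post")
        traj = run_dfba(model, rules, gene, **(dfba_kwargs or {}))
        return 0.0 if traj.post_rate is None else traj.post_rate

    records = []
    for gene in sorted(set(genes)):
        g_a = _post_growth(rules_a, gene)
        g_b = _post_growth(rules_b, gene)
        pre_a = phase_growth(model, rules_a, gene, "pre")
        pre_b = phase_growth(model, rules_b, gene, "pre")
        viable = max(g_a, g_b, pre_a, pre_b) > 1e-9
        if not viable:
            continue
        records.append({
            "gene": gene, "growth_a": g_a, "growth_b": g_b,
            "abs_diff": abs(g_b - g_a),
        })
    table = pd.DataFrame.from_records(records, columns=["gene", "growth_a", "growth_b", "abs_diff"])
    table = table.sort_values(["abs_diff", "gene"], ascending=[False, True], kind="mergesort")
    table = table.reset_index(drop=True)
    if top_k is not None:
        table = table.head(top_k)
    return table


# ---------------------------------------------------------------------------
# Replicate simulations


def replicate_fluxes(
    model: StoichiometricModel,
    rule_set: RegulatoryRuleSet | None,
    knockout_gene: str | None,
    phase: str,
    n_replicates: int = 13,
    jitter_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Flux matrix (reactions x replicates) from jittered FBA solves.

    Each replicate multiplies every exchange-reaction bound by an
    independent Uniform(1-j, 1+j) factor before solving, emulating
    replicate-to-replicate variation in the simulated environment.  With
    a shared seed, replicate columns are paired across calls (the same
    jitter factors are applied), which is what downstream paired tests
    assume.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    exchange_ids = [r.id for r in model.cobra_model.exchanges]
    cols = {}
    n_feasible = 0
    for i in range(n_replicates):
        factors = rng.uniform(1 - jitter_fraction, 1 + jitter_fraction, size=len(exchange_ids))
        overrides = {}
        medium = model.phase_media.get(phase, {})
        for rid, f in zip(exchange_ids, factors):
            lb, ub = medium.get(rid, model.cobra_model.reactions.get_by_id(rid).bounds)
            overrides[rid] = (lb * f, ub * f)
        sol = solve_fba(model, rule_set, knockout_gene, phase, exchange_bounds=overrides)
        if sol.status == "optimal":
            n_feasible += 1
        cols[f"rep{i}"] = sol.fluxes
    if n_feasible == 0:
        raise RuntimeError("all replicate FBA problems were infeasible")
    return pd.DataFrame(cols, index=model.reaction_ids)


# ---------------------------------------------------------------------------
# I/O


def write_sbml(model: StoichiometricModel, path) -> None:
    cobra.io.write_sbml_model(model.cobra_model, str(path))


def read_sbml(path, biomass_id: str | None = None,
              regulator_genes: tuple[str, ...] = (),
              phase_media: dict | None = None) -> StoichiometricModel:
    """Read an SBML model; study annotations are supplied by the caller.

    The diauxic phase media of toy models follow the exchange-id
    convention ``EX_glc_e`` / ``EX_eth_e``; :func:`diauxic_phase_media`
    rebuilds them when none are given.
    """
    m = cobra.io.read_sbml_model(str(path))
    if biomass_id is None:
        objective_rxns = [r.id for r in m.reactions if r.objective_coefficient]
        if len(objective_rxns) != 1:
            raise ValueError(
                f"cannot infer the biomass reaction (candidates: {objective_rxns}); "
                "pass biomass_id explicitly")
        biomass_id = objective_rxns[0]
    sm = StoichiometricModel(cobra_model=m, biomass_id=biomass_id,
                             regulator_genes=tuple(regulator_genes),
                             phase_media=phase_media or {})
    if not sm.phase_media:
        sm.phase_media = diauxic_phase_media(sm)
    sm.validate()
    return sm


def diauxic_phase_media(model: StoichiometricModel,
                        glucose_exchange: str = "EX_glc_e",
                        ethanol_exchange: str = "EX_eth_e",
                        glucose_uptake: float = 10.0,
                        ethanol_uptake: float = 6.0) -> dict:
    """Static media for the two phases of a diauxic toy model.

    Pre-shift: glucose available, ethanol uptake repressed.  Post-shift:
    glucose exhausted, ethanol available.
    """
    rxns = set(model.reaction_ids)
    if glucose_exchange not in rxns or ethanol_exchange not in rxns:
        raise ValueError("model lacks the expected glucose/ethanol exchange reactions")
    return {
        "pre": {glucose_exchange: (-glucose_uptake, 0.0),
                ethanol_exchange: (0.0, 1000.0)},
        "post": {glucose_exchange: (0.0, 0.0),
                 ethanol_exchange: (-ethanol_uptake, 1000.0)},
    }


def write_rules_tsv(rule_set: RegulatoryRuleSet, path) -> None:
    df = pd.DataFrame(
        [(r.gene, r.phase, r.reaction, r.action, r.factor) for r in rule_set.rules],
        columns=["gene", "phase", "reaction", "action", "factor"],
    )
    with open(path, "w") as fh:
        fh.write(f"# model_label={rule_set.model_label}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_rules_tsv(path) -> RegulatoryRuleSet:
    with open(path) as fh:
        first = fh.readline().strip()
        label = first.split("=", 1)[1] if first.startswith("# model_label=") else "unnamed"
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    rules = tuple(
        RegulatoryRule(gene=row.gene, phase=row.phase, reaction=row.reaction,
                       action=row.action, factor=float(row.factor))
        for row in df.itertuples()
    )
    return RegulatoryRuleSet(model_label=label, rules=rules)
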