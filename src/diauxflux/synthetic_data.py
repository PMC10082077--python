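"""Synthetic study inputs with known ground truth.

Everything the pipeline consumes can be generated here: a toy
stoichiometric model pair whose two regulatory rule sets (labelled M1 and
M1Smart) differ by planted rules, two-phase diauxic growth curves,
structured LC-MS peak tables with batch effects, injection-order drift,
QC/blank samples and planted differential features, and typed
metabolite-pathway knowledge graphs with planted enriched pathways.

The generators are deterministic given a seed, and each returns a
:class:`GroundTruth` describing exactly what was planted so recovery can
be tested downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
import networkx as nx
import numpy as np
import pandas as pd
from cobra import Metabolite, Reaction

from .fba_engine import (
    RegulatoryRule,
    RegulatoryRuleSet,
    StoichiometricModel,
    diauxic_phase_media,
    phase_growth,
)
from .metabolomics_preprocess import PeakTable


@dataclass
class GroundTruth:
    """What a generator planted, for downstream recovery checks."""

    #: genes whose knockout changes post-shift growth under exactly one variant
    affected_genes: set = field(default_factory=set)
    #: the affected gene with the largest planted growth discrepancy
    primary_affected_gene: str | None = None
    #: feature_id -> signed log2 fold change (and the condition it applies to)
    true_diff_features: dict = field(default_factory=dict)
    #: batch -> drift polynomial coefficients (in injection order)
    drift_profiles: dict = field(default_factory=dict)
    #: pathway node ids planted as enriched
    enriched_pathways: set = field(default_factory=set)
    #: pathway -> member compound node ids (knowledge-graph generator only)
    pathway_compounds: dict = field(default_factory=dict)


@dataclass
class SimDesign:
    """Design of a synthetic metabolomics study.

    Defaults emulate a small two-batch study: a handful of strains
    sampled in both diauxic phases with six replicates per condition
    (typical metabolomics designs use three to six), pooled QCs injected every
    ``qc_interval`` study samples plus at the start and end of each
    batch, and two blanks per batch.
    """

    n_strains: int = 4
    replicates_per_condition: int = 6
    n_batches: int = 2
    qc_interval: int = 5
    n_features: int = 100
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.replicates_per_condition < 2:
            raise ValueError("replicates_per_condition must be >= 2")
        if self.qc_interval < 2:
            raise ValueError("qc_interval must be >= 2")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# Toy model pair


def _build_toy_model(chain_len: int, resp_cap: float, rng: np.random.Generator) -> StoichiometricModel:
    """Minimal diauxic network: glycolysis chain, fermentation, respiration.

    Glucose is catabolized to pyruvate with a small ATP yield; excess
    pyruvate is fermented to ethanol (exported); ethanol can be respired
    (capacity-limited, high ATP yield) and regenerated into pyruvate via a
    gluconeogenic route, supporting slower post-shift growth on ethanol.
    """
    m = cobra.Model("diauxic_toy")
    mets = {mid: Metabolite(mid, compartment="c") for mid in
            ["glc_c", "pyr_c", "eth_c", "atp_c", "co2_c"]}
    for mid in ["glc_e", "eth_e", "co2_e"]:
        mets[mid] = Metabolite(mid, compartment="e")
    chain = [Metabolite(f"gi{i}_c", compartment="c") for i in range(chain_len)]

    def rxn(rid, stoich, lb, ub, gpr=""):
        r = Reaction(rid)
        r.add_metabolites(stoich)
        r.bounds = (lb, ub)
        m.add_reactions([r])
        if gpr:
            r.gene_reaction_rule = gpr
        return r

    rxn("EX_glc_e", {mets["glc_e"]: -1}, -10.0, 0.0)
    rxn("EX_eth_e", {mets["eth_e"]: -1}, 0.0, 1000.0)
    rxn("EX_co2_e", {mets["co2_e"]: -1}, 0.0, 1000.0)
    rxn("GLCt", {mets["glc_e"]: -1, mets["glc_c"]: 1}, 0.0, 1000.0, "HXT1")
    rxn("ETHt", {mets["eth_c"]: -1, mets["eth_e"]: 1}, -1000.0, 1000.0)
    rxn("CO2t", {mets["co2_c"]: -1, mets["co2_e"]: 1}, 0.0, 1000.0)

    # glycolysis: glc_c -> [chain] -> 2 pyr + 2 atp
    prev = mets["glc_c"]
    for i, met in enumerate(chain):
        rxn(f"GLY{i + 1}", {prev: -1, met: 1}, 0.0, 1000.0, f"GLY{i + 1}G")
        prev = met
    rxn("GLYF", {prev: -1, mets["pyr_c"]: 2, mets["atp_c"]: 2}, 0.0, 1000.0,
        "CDC19 and PGK1")
    rxn("FERM", {mets["pyr_c"]: -1, mets["eth_c"]: 1, mets["co2_c"]: 1},
        0.0, 1000.0, "PDC1 or PDC5")
    rxn("RESP", {mets["eth_c"]: -1, mets["atp_c"]: 3, mets["co2_c"]: 2},
        0.0, resp_cap, "ADH2 and CIT1")
    rxn("GNG", {mets["eth_c"]: -2, mets["atp_c"]: -2, mets["pyr_c"]: 1,
                mets["co2_c"]: 1}, 0.0, 1000.0, "ICL1")
    rxn("BIOMASS", {mets["pyr_c"]: -10, mets["atp_c"]: -40}, 0.0, 1000.0)

    m.objective = "BIOMASS"
    sm = StoichiometricModel(cobra_model=m, biomass_id="BIOMASS")
    sm.phase_media = diauxic_phase_media(sm)
    return sm


def make_toy_model_pair(
    n_internal_mets: int = 8,
    n_regulator_genes: int = 6,
    seed: int = 0,
    max_retries: int = 5,
) -> tuple[StoichiometricModel, RegulatoryRuleSet, RegulatoryRuleSet, GroundTruth]:
    """A toy model plus two regulatory rule sets differing by planted rules.

    M1 and M1Smart share a background rule; M1Smart additionally knows
    that one regulator gene (drawn from the seeded pool) is required
    post-shift for ethanol utilization -- its knockout abolishes
    post-shift growth under M1Smart but not under M1 -- and that a second
    regulator sustains full respiratory capacity post-shift, whose
    knockout merely reroutes flux and slows growth.  These are the
    planted discrepancies that strain ranking and the flux-rerouting
    statistics should recover.
    """
    if n_internal_mets < 4:
        raise ValueError("n_internal_mets must be >= 4")
    if n_regulator_genes < 3:
        raise ValueError("n_regulator_genes must be >= 3")
    rng = np.random.default_rng(seed)
    chain_len = max(0, n_internal_mets - 5)

    for attempt in range(max_retries):
        resp_cap = float(rng.uniform(4.0, 6.0))
        regulators = tuple(f"REG{i + 1}" for i in range(n_regulator_genes))
        affected, secondary, background_gene = (
            str(g) for g in rng.choice(regulators, size=3, replace=False))

        model = _build_toy_model(chain_len, resp_cap, rng)
        model.regulator_genes = regulators

        shared = (
            RegulatoryRule(gene=background_gene, phase="pre", reaction="RESP",
                           action="scale_bound", factor=float(rng.uniform(0.4, 0.8))),
        )
        rules_m1 = RegulatoryRuleSet(model_label="M1", rules=shared)
        rules_m1smart = RegulatoryRuleSet(
            model_label="M1Smart",
            rules=shared + (
                RegulatoryRule(gene=affected, phase="post", reaction="ETHt",
                               action="disable"),
                RegulatoryRule(gene=secondary, phase="post", reaction="RESP",
                               action="scale_bound",
                               factor=float(rng.uniform(0.3, 0.5))),
            ),
        )
        rules_m1.validate_for(model)
        rules_m1smart.validate_for(model)

        wt_ok = all(
            phase_growth(model, rs, None, ph) > 1e-6
            for rs in (rules_m1, rules_m1smart) for ph in ("pre", "post")
        )
        # the planted ordering must hold: the disable rule's growth
        # discrepancy strictly exceeds the scale rule's, which exceeds 0
        d_primary = abs(phase_growth(model, rules_m1smart, affected, "post")
                        - phase_growth(model, rules_m1, affected, "post"))
        d_secondary = abs(phase_growth(model, rules_m1smart, secondary, "post")
                          - phase_growth(model, rules_m1, secondary, "post"))
        if wt_ok and d_primary > d_secondary > 1e-9:
            truth = GroundTruth(affected_genes={affected, secondary},
                                primary_affected_gene=affected)
            return model, rules_m1, rules_m1smart, truth
    raise RuntimeError(
        f"could not generate a viable toy model pair in {max_retries} attempts")


# ---------------------------------------------------------------------------
# Growth curves


@dataclass
class SimGrowthCurve:
    time: np.ndarray
    od: np.ndarray
    pre_rate: float
    post_rate: float
    shift_time: float


def simulate_growth_curve(
    pre_rate: float = 0.4,
    post_rate: float = 0.1,
    shift_time: float = 12.0,
    lag: float = 1.0,
    od0: float = 0.05,
    noise_sd: float = 0.0,
    dt: float = 1.0 / 3.0,
    horizon: float = 48.0,
    seed: int = 0,
) -> SimGrowthCurve:
    """Piecewise-exponential diauxic OD trace with a lag plateau at the shift.

    OD grows exponentially at ``pre_rate`` until ``shift_time``, plateaus
    for ``lag`` hours, then resumes at ``post_rate``.  Gaussian reading
    noise is added and values are clipped to the instrument range [0, 2].
    The 20-minute default sampling matches a plate-reader protocol.
    """
    if pre_rate <= 0 or post_rate < 0 or horizon <= 0 or dt <= 0:
        raise ValueError("rates and horizon must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, horizon + dt / 2, dt)
    od = np.empty_like(t)
    od_shift = od0 * np.exp(pre_rate * shift_time)
    pre = t <= shift_time
    plateau = (t > shift_time) & (t <= shift_time + lag)
    post = t > shift_time + lag
    od[pre] = od0 * np.exp(pre_rate * t[pre])
    od[plateau] = od_shift
    od[post] = od_shift * np.exp(post_rate * (t[post] - shift_time - lag))
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    od = np.clip(od, 0.0, 2.0)
    return SimGrowthCurve(time=t, od=od, pre_rate=pre_rate, post_rate=post_rate,
                          shift_time=shift_time)


# ---------------------------------------------------------------------------
# Peak tables


def _default_strains(n: int) -> list[str]:
    return ["WT"] + [f"KO{i}" for i in range(1, n)]


def simulate_peak_table(
    design: SimDesign,
    effects: list[dict] | None = None,
    strains: list[str] | None = None,
    sigma_log2: float = 0.3,
    batch_sd_log2: float = 0.3,
    drift_amplitude: float = 0.15,
    qc_sigma_log2: float = 0.05,
    blank_log2_offset: float = -7.0,
    paired_noise: bool = False,
) -> tuple[PeakTable, GroundTruth]:
    """Log-normal peak intensities with batch, drift and planted effects.

    Each effect is a dict ``{"feature": id, "log2fc": x}`` plus optional
    ``"phase"`` and/or ``"strain"`` keys restricting the condition it
    applies to (an effect with ``phase="post"`` and no strain applies to
    every strain post-shift; one with both keys applies to that strain in
    that phase only).

    Intensities are ``2**(mu_f + batch + drift + effect + eps)``.  The
    injection-order drift is a per-batch quadratic applied identically to
    QC and study samples, which is the representativeness assumption
    QC-RLSC relies on.  Missing values are planted as zeros in study
    samples.  With ``paired_noise=True`` the residual ``eps`` is drawn
    once per (feature, batch, phase, replicate index) and shared across
    strains: strains without a planted effect are then observationally
    identical to the reference strain, giving exact nulls for closed-loop
    validation experiments.
    """
    rng = np.random.default_rng(design.seed)
    strains = strains or _default_strains(design.n_strains)
    if len(strains) != design.n_strains:
        raise ValueError("strains list length must equal design.n_strains")
    features = [f"F{i + 1:04d}" for i in range(design.n_features)]
    effects = effects or []
    for e in effects:
        if e["feature"] not in features:
            raise ValueError(f"effect spec references unknown feature {e['feature']!r}")
        if float(e["log2fc"]) == 0.0:
            raise ValueError("planted log2 fold changes must be nonzero")

    # per-feature baseline (log2 of a typical LC-MS intensity) and metadata
    mu = rng.normal(16.0, 2.0, size=design.n_features)
    fmeta = pd.DataFrame({
        "mz": np.round(rng.uniform(60.0, 1200.0, size=design.n_features), 4),
        "rt": np.round(rng.uniform(0.5, 10.0, size=design.n_features), 3),
        "adduct": rng.choice(["[M+H]+", "[M+Na]+"], size=design.n_features, p=[0.8, 0.2]),
        "identification": [f"cmpd_{f}" for f in features],
    }, index=pd.Index(features, name="feature_id"))

    batch_shift = rng.normal(0.0, batch_sd_log2, size=(design.n_batches, design.n_features))
    drift_profiles = {}
    conditions = [(s, ph) for s in strains for ph in ("pre", "post")]
    # round-robin conditions over batches; replicates split evenly
    reps_per_batch = int(np.ceil(design.replicates_per_condition / design.n_batches))

    sample_rows, columns, col_ids = [], [], []
    truth_effects = {e["feature"]: float(e["log2fc"]) for e in effects}
    shared_eps: dict = {}
    feat_idx = {f: j for j, f in enumerate(features)}
    eff_cache: dict = {}
    for s, ph in conditions:
        eff = np.zeros(design.n_features)
        for e in effects:
            if "phase" in e and e["phase"] != ph:
                continue
            if "strain" in e and e["strain"] != s:
                continue
            eff[feat_idx[e["feature"]]] += float(e["log2fc"])
        eff_cache[(s, ph)] = eff
    for b in range(design.n_batches):
        # quadratic drift in injection order, shared by QCs and samples
        c1 = rng.uniform(-drift_amplitude, drift_amplitude)
        c2 = rng.uniform(-drift_amplitude, drift_amplitude) / 2
        drift_profiles[f"B{b + 1}"] = (0.0, c1, c2)
        injections = []  # (sample_id, class, strain, phase, rep_index)
        for i in range(2):
            injections.append((f"B{b + 1}_blank{i + 1}", "blank", "", "", -1))
        study = []
        for s, ph in conditions:
            lo = b * reps_per_batch
            hi = min(design.replicates_per_condition, (b + 1) * reps_per_batch)
            for r in range(lo, hi):
                study.append((f"B{b + 1}_{s}_{ph}_r{r + 1}", "sample", s, ph, r))
        qc_count = 0

        def _qc():
            nonlocal qc_count
            qc_count += 1
            return (f"B{b + 1}_QC{qc_count}", "QC", "", "", -1)

        injections.append(_qc())
        for i, row in enumerate(study):
            injections.append(row)
            if (i + 1) % design.qc_interval == 0 and i + 1 < len(study):
                injections.append(_qc())
        injections.append(_qc())

        n_inj = len(injections)
        orders = np.arange(1, n_inj + 1, dtype=float)
        x = (orders - 1) / max(n_inj - 1, 1)  # normalized injection position
        drift = c1 * x + c2 * x**2  # log2-scale drift

        for inj_idx, ((sid, cls, s, ph, rep), d) in enumerate(zip(injections, drift)):
            base = mu + batch_shift[b]
            if cls == "blank":
                vals = 2.0 ** (mu + blank_log2_offset
                               + rng.normal(0.0, sigma_log2, design.n_features))
            elif cls == "QC":
                vals = 2.0 ** (base + d + rng.normal(0.0, qc_sigma_log2, design.n_features))
            else:
                eff = eff_cache[(s, ph)]
                if paired_noise:
                    key = (b, ph, rep)
                    if key not in shared_eps:
                        shared_eps[key] = rng.normal(0.0, sigma_log2, design.n_features)
                    eps = shared_eps[key]
                else:
                    eps = rng.normal(0.0, sigma_log2, design.n_features)
                vals = 2.0 ** (base + d + eff + eps)
                if design.missing_rate > 0:
                    vals = np.where(rng.random(design.n_features) < design.missing_rate,
                                    0.0, vals)
            columns.append(vals)
            col_ids.append(sid)
            sample_rows.append({"sample_id": sid, "batch": f"B{b + 1}",
                                "injection_order": inj_idx + 1,
                                "class": cls, "strain": s, "phase": ph})

    smeta = pd.DataFrame(sample_rows).set_index("sample_id")
    intens = pd.DataFrame(np.column_stack(columns),
                          index=fmeta.index, columns=pd.Index(col_ids, name="sample_id"))
    table = PeakTable(intens, fmeta, smeta)
    truth = GroundTruth(true_diff_features=truth_effects, drift_profiles=drift_profiles)
    return table, truth


# ---------------------------------------------------------------------------
# Knowledge graphs


def make_knowledge_graph(
    n_pathways: int = 6,
    n_compounds: int = 40,
    seed: int = 0,
    n_planted: int = 1,
    compounds_per_pathway: tuple[int, int] = (4, 7),
    max_retries: int = 5,
) -> tuple[nx.Graph, GroundTruth]:
    """Typed pathway-reaction-compound graph with planted enriched pathways.

    Each pathway owns a few reactions, each reaction touches compounds
    from the pathway's member pool.  Planted pathways get exclusive
    compound pools (>= 3 compounds, disjoint from the designated decoy
    pathway ``P_decoy`` and from the shared background pool) so an input
    set drawn from a planted pathway's compounds is unambiguously
    enriched there.  Pathways are chained with ``hierarchy`` edges to
    guarantee connectivity.
    """
    if n_pathways < 2:
        raise ValueError("n_pathways must be >= 2")
    if n_planted >= n_pathways:
        raise ValueError("need at least one non-planted pathway")
    rng = np.random.default_rng(seed)

    for attempt in range(max_retries):
        g = nx.Graph()
        compounds = [f"C{i + 1:03d}" for i in range(n_compounds)]
        for c in compounds:
            g.add_node(c, type="compound")
        pathways = [f"P{i + 1}" for i in range(n_pathways)]
        planted = set(pathways[:n_planted])
        for p in pathways:
            g.add_node(p, type="pathway")

        lo, hi = compounds_per_pathway
        # reserve exclusive pools for planted pathways
        pool = list(compounds)
        rng.shuffle(pool)
        membership = {}
        idx = 0
        for p in pathways[:n_planted]:
            k = int(rng.integers(max(lo, 3), hi + 1))
            membership[p] = pool[idx:idx + k]
            idx += k
        shared = pool[idx:]
        for p in pathways[n_planted:]:
            k = min(int(rng.integers(lo, hi + 1)), len(shared))
            membership[p] = list(rng.choice(shared, size=k, replace=False))

        rid = 0
        truth_members = {}
        for p in pathways:
            members = membership[p]
            truth_members[p] = list(members)
            n_rxn = max(2, len(members) // 2)
            for _ in range(n_rxn):
                rid += 1
                r = f"R{rid:03d}"
                g.add_node(r, type="reaction")
                g.add_edge(p, r, edge_type="pathway_reaction", weight=1.0)
                k = int(rng.integers(2, min(4, len(members)) + 1))
                for c in rng.choice(members, size=k, replace=False):
                    g.add_edge(r, c, edge_type="reaction_compound", weight=1.0)
            # make sure every member compound is attached
            for c in members:
                if g.degree(c) == 0 or not any(
                        g.nodes[n]["type"] == "reaction" for n in g.neighbors(c)):
                    rid += 1
                    r = f"R{rid:03d}"
                    g.add_node(r, type="reaction")
                    g.add_edge(p, r, edge_type="pathway_reaction", weight=1.0)
                    g.add_edge(r, c, edge_type="reaction_compound", weight=1.0)
        # drop compounds used by no pathway, then chain pathways
        isolated = [c for c in compounds if g.degree(c) == 0]
        g.remove_nodes_from(isolated)
        for a, b in zip(pathways, pathways[1:]):
            g.add_edge(a, b, edge_type="hierarchy", weight=0.5)

        if nx.is_connected(g):
            truth = GroundTruth(enriched_pathways=planted,
                                pathway_compounds=truth_members)
            return g, truth
    raise RuntimeError(f"could not generate a connected graph in {max_retries} attempts")


def write_graph_tsv(g: nx.Graph, edge_path, node_path) -> None:
    edges = pd.DataFrame(
        [(u, v, d.get("edge_type", "")) for u, v, d in g.edges(data=True)],
        columns=["source_id", "target_id", "edge_type"],
    ).sort_values(["source_id", "target_id"], kind="mergesort")
    edges.to_csv(edge_path, sep="\t", index=False)
    nodes = pd.DataFrame(
        [(n, d["type"]) for n, d in g.nodes(data=True)],
        columns=["node_id", "node_type"],
    ).sort_values("node_id", kind="mergesort")
    nodes.to_csv(node_path, sep="\t", index=False)


def read_graph_tsv(edge_path, node_path) -> nx.Graph:
    g = nx.Graph()
    nodes = pd.read_csv(node_path, sep="\t")
    for row in nodes.itertuples():
        g.add_node(row.node_id, type=row.node_type)
    edges = pd.read_csv(edge_path, sep="\t")
    for row in edges.itertuples():
        g.add_edge(row.source_id, row.target_id, edge_type=row.edge_type, weight=1.0)
    return g
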