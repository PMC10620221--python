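"""Synthetic inputs with known ground truth for every pipeline stage.

Nothing in the real study is publicly deposited (prior-knowledge networks,
Human Protein Atlas snapshots, raw plate readings), so this module generates
structurally analogous stand-ins:

* two overlapping "published" signaling networks with a layered
  ligand → receptor → secondary-messenger → transcription-factor → output
  architecture and, optionally, a planted bottleneck mediator that carries
  more admissible input→output simple paths than any other intermediate (the
  in-silico analogue of an influential signaling hub),
* a gene × cell-type expression table with cell-specific dropout,
* simulated immunoassay plates (8-point, 2-fold standard series; signals from
  per-analyte 4PL forward models with multiplicative noise),
* dose–response secretion studies over effector:target ratios with
  programmed treatment effects (responsive, refractory, and null analytes)
  and the 3-experiments × triplicate replicate structure.

Every generator is a pure function of its scenario (seed included):
identical inputs give identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ScenarioError
from .expression import ExpressionTable
from .network import SignalingNetwork, network_from_edges
from .pruning import MediatorPanel, enumerate_simple_paths
from .quant import PlateMeasurement, four_pl

#: The 27-analyte inflammatory cytokine panel measured by the multiplex assay.
PANEL_27 = (
    "FGF basic", "IFN-γ", "IL-4", "IL-8", "IL-13", "MCP-1", "RANTES",
    "Eotaxin", "IL-1β", "IL-5", "IL-9", "IL-15", "MIP-1a", "TNF-a",
    "G-CSF", "IL-1ra", "IL-6", "IL-10", "IL-17", "MIP-1b", "VEGF",
    "GM-CSF", "IL-2", "IL-7", "IL-12 (p70)", "IP-10", "PDGF-BB",
)

#: Input mediators: T-cell-derived cytokines released on CAR engagement.
DEFAULT_INPUTS = ("IFN-γ", "IL-2", "GM-CSF", "TNF-a", "IL-15")
#: Output mediators: cytokines measured downstream at the
#: macrophage–endothelial interface.
DEFAULT_OUTPUTS = ("IL-6", "IL-8", "MCP-1", "MIP-1a", "VEGF", "G-CSF")


# ===================================================================
# Network scenarios
# ===================================================================


@dataclass(frozen=True)
class NetworkScenario:
    """Parameters of a planted-bottleneck network family.

    ``multiplicity`` is the number of upstream nodes wired into the planted
    mediator (its bottleneck in-degree); 0 plants nothing.  Background edges
    respect the layer order at probability ``edge_density``.
    """

    seed: int = 0
    n_receptors: int = 8
    n_messengers: int = 8
    n_tfs: int = 6
    inputs: tuple[str, ...] = DEFAULT_INPUTS
    outputs: tuple[str, ...] = DEFAULT_OUTPUTS
    planted_id: str = "STAT3"
    multiplicity: int = 12
    edge_density: float = 0.08
    component_names: tuple[str, str] = ("macrophage_model", "endothelial_model")


@dataclass
class NetworkGroundTruth:
    """What the generator planted, for recovery tests."""

    planted_id: str | None
    path_counts: dict[str, int] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {"planted_id": self.planted_id, "path_counts": self.path_counts}


@dataclass
class NetworkBundle:
    components: tuple[SignalingNetwork, SignalingNetwork]
    panel: MediatorPanel
    ground_truth: NetworkGroundTruth


def _intermediate_path_counts(
    network: SignalingNetwork, panel: MediatorPanel, max_nodes: int = 8
) -> dict[str, int]:
    """Number of admissible input→output simple paths through each intermediate."""
    pathset = enumerate_simple_paths(network, panel, max_nodes)
    counts: dict[str, int] = {}
    for p in pathset.paths:
        for node in p[1:-1]:
            counts[node] = counts.get(node, 0) + 1
    return counts


def generate_networks(scenario: NetworkScenario) -> NetworkBundle:
    """Generate two overlapping component networks and the mediator panel.

    The layered architecture routes ligands through receptors, secondary
    messengers, and transcription factors to output mediators.  With
    ``multiplicity`` > 0, the planted mediator (a transcription factor)
    receives edges from ``multiplicity`` upstream receptor/messenger nodes and
    feeds every output, making it the dominant bottleneck; this is verified
    post hoc by counting paths through every intermediate, and a scenario
    whose planted node is not strictly dominant raises :class:`ScenarioError`.
    """
    rng = np.random.default_rng(scenario.seed)
    receptors = [f"REC_{i+1:02d}" for i in range(scenario.n_receptors)]
    messengers = [f"MSG_{i+1:02d}" for i in range(scenario.n_messengers)]
    tfs = [f"TF_{i+1:02d}" for i in range(scenario.n_tfs)]
    inputs, outputs = list(scenario.inputs), list(scenario.outputs)
    if scenario.multiplicity > 0:
        upstream_pool = receptors + messengers
        if scenario.multiplicity > len(upstream_pool):
            raise ScenarioError(
                f"multiplicity {scenario.multiplicity} exceeds the "
                f"{len(upstream_pool)} available upstream nodes"
            )

    edges: list[tuple[str, str, str]] = []
    # guaranteed backbone connectivity
    for i, lig in enumerate(inputs):
        edges.append((lig, receptors[i % len(receptors)], "binds"))
    for i, rec in enumerate(receptors):
        edges.append((rec, messengers[int(rng.integers(len(messengers)))], "activates"))
    for i, msg in enumerate(messengers):
        edges.append((msg, tfs[int(rng.integers(len(tfs)))], "activates"))
    for i, tf in enumerate(tfs):
        edges.append((tf, outputs[int(rng.integers(len(outputs)))], "induces"))
    # background layer-respecting edges
    layer_pairs = [
        (inputs, receptors, "binds"),
        (receptors, messengers, "activates"),
        (messengers, tfs, "activates"),
        (tfs, outputs, "induces"),
        (messengers, messengers, "modulates"),
    ]
    for upper, lower, label in layer_pairs:
        for u in upper:
            for v in lower:
                if u != v and rng.random() < scenario.edge_density:
                    edges.append((u, v, label))
    # planted bottleneck
    planted = None
    if scenario.multiplicity > 0:
        planted = scenario.planted_id
        chosen = list(rng.permutation(upstream_pool)[: scenario.multiplicity])
        for u in chosen:
            edges.append((u, planted, "activates"))
        for out in outputs:
            edges.append((planted, out, "induces"))

    roles = {n: "ligand" for n in inputs}
    roles.update({n: "receptor" for n in receptors})
    roles.update({n: "secondary-messenger" for n in messengers})
    roles.update({n: "transcription-factor" for n in tfs})
    roles.update({n: "other" for n in outputs})
    if planted:
        roles[planted] = "transcription-factor"

    # split into two overlapping components: each edge goes to A, B, or both
    edges = sorted(set(edges))
    assignment = rng.choice(3, size=len(edges), p=[0.35, 0.35, 0.30])
    name_a, name_b = scenario.component_names
    comp_edges = {name_a: [], name_b: []}
    for e, which in zip(edges, assignment):
        if which in (0, 2):
            comp_edges[name_a].append(e)
        if which in (1, 2):
            comp_edges[name_b].append(e)
    components = tuple(
        network_from_edges(
            comp_edges[name],
            roles={n: roles[n] for n in
                   {x for e in comp_edges[name] for x in e[:2]}},
            name=name, provenance=name,
        )
        for name in (name_a, name_b)
    )

    panel = MediatorPanel.from_lists(inputs, outputs)
    merged = network_from_edges(edges, roles=roles, name="merged")
    counts = _intermediate_path_counts(merged, panel)
    if planted is not None:
        best_other = max(
            (v for k, v in counts.items() if k != planted), default=0
        )
        if counts.get(planted, 0) <= best_other:
            raise ScenarioError(
                f"planted mediator {planted!r} lies on {counts.get(planted, 0)} "
                f"paths, not strictly more than the best other ({best_other})"
            )
    return NetworkBundle(components, panel, NetworkGroundTruth(planted, counts))


def generate_expression(
    scenario: NetworkScenario,
    network: SignalingNetwork,
    cell_types: tuple[str, ...] = ("endothelial", "macrophage"),
    dropout: float | dict[str, float] = 0.3,
    designated_cell: str | None = None,
) -> ExpressionTable:
    """Expression table over the network's nodes with cell-specific dropout.

    The planted mediator and all panel-name nodes are always expressed in
    ``designated_cell`` (default: the first cell type); a seeded ``dropout``
    fraction of the remaining nodes is zeroed per cell type; nonzero
    abundances are log-normal around ~20 units (comfortably above the
    conventional >1 expression call).
    """
    if isinstance(dropout, dict):
        rates = {c: float(dropout.get(c, 0.0)) for c in cell_types}
    else:
        rates = {c: float(dropout) for c in cell_types}
    for c, r in rates.items():
        if not 0 <= r < 1:
            raise ValueError(f"dropout for {c!r} must be in [0, 1), got {r}")
    designated = designated_cell or cell_types[0]
    rng = np.random.default_rng(scenario.seed + 1)
    protected = {scenario.planted_id, *scenario.inputs, *scenario.outputs}
    records = []
    for cell in cell_types:
        for node_id in network.node_ids:
            always_on = cell == designated and node_id in protected
            if not always_on and rng.random() < rates[cell]:
                abundance = 0.0
            else:
                abundance = float(rng.lognormal(mean=3.0, sigma=1.0))
            records.append((node_id, cell, abundance))
    return ExpressionTable.from_records(records)


# ===================================================================
# Secretion scenarios
# ===================================================================

#: Analytes whose secretion scales with CAR T-cell dose and is attenuated by
#: treatment (macrophage-type program).
TREATMENT_RESPONSIVE = ("IL-1β", "IL-1ra", "TNF-a", "MIP-1a", "MIP-1b", "IL-10")
#: Dose-responsive analytes whose secretion ignores the treatment flag
#: (endothelial-type program refractory to corticosteroid).
TREATMENT_REFRACTORY = ("IL-6", "IL-8", "MCP-1", "VEGF", "GM-CSF")
#: Attenuation applied to responsive analytes under treatment.
TREATMENT_ATTENUATION = 0.2


@dataclass(frozen=True)
class Condition:
    """One experimental condition of the secretion study."""

    name: str
    system: str = "co-culture"
    stimulus: str = "ccm"  # "media" | "lps" | "ccm"
    dose: float | None = None  # numeric E:T ratio for ccm
    treatment: str = "none"  # "none" | "dexamethasone" | "ruxolitinib" | "combination"


@dataclass(frozen=True)
class ConditionDesign:
    """Condition set plus the replicate structure (N experiments × n wells)."""

    conditions: tuple[Condition, ...]
    n_experiments: int = 3
    n_replicates: int = 3

    def __post_init__(self):
        if self.n_experiments < 1 or self.n_replicates < 1:
            raise ValueError("replicate structure requires N >= 1 and n >= 1")
        names = [c.name for c in self.conditions]
        if len(names) != len(set(names)):
            raise ValueError("condition names must be unique")


def default_design(doses: tuple[float, ...] = (0.2, 1.0, 5.0)) -> ConditionDesign:
    """Media/LPS controls plus a conditioned-media dose series, N = 3 × 3."""
    conditions = [
        Condition("media", stimulus="media"),
        Condition("LPS", stimulus="lps"),
    ]
    for d in doses:
        conditions.append(Condition(f"CCM {d:g}:1", stimulus="ccm", dose=d))
    return ConditionDesign(tuple(conditions))


@dataclass(frozen=True)
class SecretionScenario:
    """Programmed ground truth of the simulated secretion studies.

    Baselines are per-analyte LPS-stimulated concentrations (pg/mL-like,
    log-normal around ~100); conditioned media at dose d scales a
    dose-responsive analyte's mean by (1 + slope·d); treatment multiplies
    responsive analytes by ``TREATMENT_ATTENUATION``.  Noise is a per-well
    multiplicative log-normal with coefficient of variation ``cv_technical``
    plus an experiment-level log-normal scale of sigma
    ``experiment_scale_sd``.
    """

    seed: int = 0
    panel: tuple[str, ...] = PANEL_27
    cv_technical: float = 0.03
    experiment_scale_sd: float = 0.10
    media_factor: float = 0.2
    lps_factor: float = 3.0
    responsive: tuple[str, ...] = TREATMENT_RESPONSIVE
    refractory: tuple[str, ...] = TREATMENT_REFRACTORY
    treatment_attenuation: float = TREATMENT_ATTENUATION

    def params(self) -> pd.DataFrame:
        """Deterministic per-analyte parameters derived from the seed."""
        rng = np.random.default_rng(self.seed + 10)
        rows = []
        dose_responsive = set(self.responsive) | set(self.refractory)
        for analyte in self.panel:
            baseline = float(rng.lognormal(mean=np.log(100.0), sigma=0.8))
            slope = (
                float(rng.uniform(0.5, 1.5)) if analyte in dose_responsive else 0.0
            )
            rows.append({
                "analyte": analyte,
                "baseline": baseline,
                "dose_slope": slope,
                "treatment_class": (
                    "responsive" if analyte in self.responsive
                    else "refractory" if analyte in self.refractory
                    else "null"
                ),
                # 4PL forward-model parameters for plate simulation
                "pl_a": float(rng.uniform(0.02, 0.08)),
                "pl_d": float(rng.uniform(2.0, 3.5)),
                "pl_b": float(rng.uniform(0.9, 1.4)),
                "pl_c": baseline * float(rng.uniform(0.8, 1.25)),
            })
        return pd.DataFrame(rows).set_index("analyte")


def true_concentration(
    scenario: SecretionScenario, params: pd.DataFrame, analyte: str, cond: Condition
) -> float:
    """Programmed noise-free mean concentration for (analyte, condition)."""
    p = params.loc[analyte]
    base = float(p["baseline"])
    if cond.stimulus == "media":
        return base * scenario.media_factor
    if cond.stimulus == "lps":
        return base * scenario.lps_factor
    dose = cond.dose if cond.dose is not None else 1.0
    mean = base * (1.0 + float(p["dose_slope"]) * dose)
    if cond.treatment != "none" and p["treatment_class"] == "responsive":
        mean *= scenario.treatment_attenuation
    return mean


def simulate_plate(
    scenario: SecretionScenario,
    conditions: tuple[Condition, ...],
    n_sample_wells: int = 3,
    noise_cv: float | None = None,
    n_standards: int = 8,
    noise_seed: int | None = None,
) -> tuple[list[PlateMeasurement], pd.DataFrame]:
    """Simulate one multiplex plate: standards plus sample wells.

    Per analyte: an ``n_standards``-point, 2-fold standard dilution series
    with top concentration 20 × the 4PL midpoint, and ``n_sample_wells``
    sample wells per condition at the programmed true concentration.  Signals
    come from the analyte's 4PL forward model with multiplicative log-normal
    noise of CV ``noise_cv`` (default: the scenario's technical CV; 0 gives
    noiseless signals).  ``noise_seed`` redraws the noise while keeping the
    scenario's programmed parameters — replicate plates of one study share
    the scenario and differ only in their noise seed.  Returns the wells and
    a true-concentration record.
    """
    cv = scenario.cv_technical if noise_cv is None else noise_cv
    rng = np.random.default_rng(
        scenario.seed + 20 if noise_seed is None else noise_seed
    )
    params = scenario.params()
    wells: list[PlateMeasurement] = []
    truth_rows = []

    def noisy(signal: float) -> float:
        if cv <= 0:
            return signal
        return float(signal * rng.lognormal(mean=0.0, sigma=cv))

    for analyte in scenario.panel:
        p = params.loc[analyte]
        a, b, c, d = (float(p[k]) for k in ("pl_a", "pl_b", "pl_c", "pl_d"))
        top = 20.0 * c
        for i in range(n_standards):
            conc = top / 2.0**i
            wells.append(PlateMeasurement(
                analyte=analyte, role="standard", nominal_conc=conc,
                signal=noisy(float(four_pl(conc, a, b, c, d))),
                well=f"STD{i+1}",
            ))
        for cond in conditions:
            true = true_concentration(scenario, params, analyte, cond)
            truth_rows.append({
                "analyte": analyte, "condition": cond.name, "true_conc": true,
            })
            for w in range(n_sample_wells):
                wells.append(PlateMeasurement(
                    analyte=analyte, role="sample",
                    signal=noisy(float(four_pl(true, a, b, c, d))),
                    condition=cond.name, well=f"{cond.name}/{w+1}",
                ))
    return wells, pd.DataFrame(truth_rows)


def simulate_secretion_study(
    scenario: SecretionScenario,
    design: ConditionDesign | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a full secretion study at the design's replicate structure.

    Returns a long-format dataset (analyte, condition, system, stimulus,
    dose, treatment, experiment, replicate, concentration) and the ground
    truth (per-analyte programmed means, slopes, and treatment classes).
    """
    design = design or default_design()
    rng = np.random.default_rng(scenario.seed + 30)
    params = scenario.params()
    rows = []
    for exp in range(1, design.n_experiments + 1):
        exp_scale = (
            float(rng.lognormal(mean=0.0, sigma=scenario.experiment_scale_sd))
            if scenario.experiment_scale_sd > 0 else 1.0
        )
        for analyte in scenario.panel:
            for cond in design.conditions:
                true = true_concentration(scenario, params, analyte, cond)
                for rep in range(1, design.n_replicates + 1):
                    noise = (
                        float(rng.lognormal(mean=0.0, sigma=scenario.cv_technical))
                        if scenario.cv_technical > 0 else 1.0
                    )
                    rows.append({
                        "analyte": analyte,
                        "condition": cond.name,
                        "system": cond.system,
                        "stimulus": cond.stimulus,
                        "dose": cond.dose,
                        "treatment": cond.treatment,
                        "experiment": exp,
                        "replicate": rep,
                        "concentration": true * exp_scale * noise,
                    })
    data = pd.DataFrame(rows)
    truth = {
        "params": params,
        "true_means": {
            (analyte, cond.name): true_concentration(scenario, params, analyte, cond)
            for analyte, cond in itertools.product(scenario.panel, design.conditions)
        },
    }
    return data, truth


def with_seed(scenario, seed: int):
    """Copy of a scenario with a different seed (scenarios are frozen)."""
    return replace(scenario, seed=seed)
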