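"""Synthetic surgical time-course data with planted ground truth.

The generator emulates a 3-time-point (0 min / 45 min / 24 h) bulk RNA-seq
study of the sham (surgery-only) response: negative-binomial counts for
eight animals per time point, with planted co-expression modules following
three temporal profiles (a transient 45-min induction, a 24-h increase and
a 24-h decrease), GO-style annotation sets concentrated in those modules,
TF target sets enriched in the planted differential transcripts, and a PPI
graph carrying a cytokine-like hub wired upstream of the driven TFs through
a short cascade.  Every downstream stage of the pipeline therefore has a
recoverable truth.

Counts follow NB(mean mu, dispersion alpha) with Var = mu + alpha * mu^2.
Within-module correlation comes from a shared per-sample latent factor:
mu_gs = b_g * 2^(effect) * exp(w * f_ms - w^2 / 2), f_ms ~ N(0, 1), which
keeps the marginal mean at b_g * 2^effect while correlating module members.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .network import InteractionGraph

PROFILES = ("transient_45min", "up_24h", "down_24h", "null")

#: biological-process category attached to each profile's planted GO terms
CATEGORY_BY_PROFILE = {
    "transient_45min": "upstream signalization",
    "up_24h": "inflammatory and immune response",
    "down_24h": "metabolism",
}
BACKGROUND_CATEGORY = "other"


@dataclass(frozen=True)
class PlantedModule:
    """A block of co-expressed transcripts sharing one temporal profile.

    ``log2_effect`` is the magnitude of the fold change on the profile's
    active group; the ``down_24h`` profile applies it with a negative sign.
    ``within_correlation`` is the latent-factor weight in [0, 1].
    """

    name: str
    size: int
    profile: str
    log2_effect: float = 0.0
    within_correlation: float = 0.4

    def __post_init__(self):
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.size < 3:
            raise ValueError("module size must be >= 3")
        if self.profile == "null" and self.log2_effect != 0:
            raise ValueError("null profile requires log2_effect = 0")
        if not (0.0 <= self.within_correlation <= 1.0):
            raise ValueError("within_correlation must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationDesign:
    """Study design for the count simulator (defaults mirror the 3 x 8 design)."""

    n_transcripts: int = 2000
    groups: tuple[str, ...] = ("0min", "45min", "24h")
    n_per_group: int = 8
    baseline_mean: float = 100.0
    dispersion: float = 0.05
    modules: tuple[PlantedModule, ...] = ()
    batch_log2_effect: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("need n_per_group >= 2")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValueError("module names must be unique")
        total = sum(m.size for m in self.modules)
        if total > self.n_transcripts:
            raise ValueError(
                f"planted modules need {total} transcripts but the design has "
                f"only {self.n_transcripts}"
            )


def default_design(seed: int = 0, n_transcripts: int = 2000) -> SimulationDesign:
    """The study conditions used throughout: three planted temporal modules."""
    return SimulationDesign(
        n_transcripts=n_transcripts,
        modules=(
            PlantedModule("M_transient", 80, "transient_45min", log2_effect=2.0),
            PlantedModule("M_up24h", 100, "up_24h", log2_effect=2.0),
            PlantedModule("M_down24h", 70, "down_24h", log2_effect=2.0),
        ),
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Planted truth for recovery tests; filled in stages by the generators."""

    module_labels: dict[str, str]          # transcript -> module name or "unassigned"
    module_profiles: dict[str, str]        # module name -> temporal profile
    de_transcripts: set[str]               # union of non-null planted modules
    term_map: dict[str, set[str]] = field(default_factory=dict)
    category_map: dict[str, str] = field(default_factory=dict)
    planted_terms: dict[str, str] = field(default_factory=dict)  # term -> module
    tf_targets: dict[str, set[str]] = field(default_factory=dict)
    driven_tfs: list[str] = field(default_factory=list)
    hub_node: str | None = None
    cascade: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        for key in ("de_transcripts",):
            payload[key] = sorted(payload[key])
        payload["term_map"] = {t: sorted(g) for t, g in self.term_map.items()}
        payload["tf_targets"] = {t: sorted(g) for t, g in self.tf_targets.items()}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        payload["de_transcripts"] = set(payload["de_transcripts"])
        payload["term_map"] = {t: set(g) for t, g in payload["term_map"].items()}
        payload["tf_targets"] = {t: set(g) for t, g in payload["tf_targets"].items()}
        return cls(**payload)


# ---------------------------------------------------------------------------
# counts


def _profile_log2_shift(profile: str, log2_effect: float, n_groups: int) -> np.ndarray:
    """Per-group log2 shift vector for a temporal profile."""
    shift = np.zeros(n_groups)
    if profile == "transient_45min":
        shift[n_groups // 2] = log2_effect
    elif profile == "up_24h":
        shift[-1] = log2_effect
    elif profile == "down_24h":
        shift[-1] = -abs(log2_effect)
    return shift


def simulate_counts(design: SimulationDesign) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw the count matrix.

    Returns (counts, metadata, truth): counts is a transcripts x samples
    integer DataFrame, metadata carries time / surgeon / batch per sample
    (surgeon and batch have no expression effect unless
    ``batch_log2_effect`` is nonzero), truth records the planted labels.
    """
    rng = np.random.default_rng(design.seed)
    G, k, n = design.n_transcripts, len(design.groups), design.n_per_group
    S = k * n

    transcripts = [f"tx{i:05d}" for i in range(G)]
    samples, times, surgeons, batches = [], [], [], []
    for gi, grp in enumerate(design.groups):
        for r in range(n):
            samples.append(f"{grp}_r{r + 1}")
            times.append(grp)
            surgeons.append(f"S{(r % 2) + 1}")
            batches.append(f"B{((gi * n + r) % 5) + 1}")
    meta = pd.DataFrame(
        {"time": times, "surgeon": surgeons, "batch": batches}, index=pd.Index(samples, name="sample")
    )

    # per-transcript baselines span a realistic dynamic range (log-normal
    # around the design's median expected count)
    baselines = rng.lognormal(mean=np.log(design.baseline_mean), sigma=1.0, size=G)

    group_of_sample = np.repeat(np.arange(k), n)
    log2_shift = np.zeros((G, k))
    labels = {t: "unassigned" for t in transcripts}
    profiles: dict[str, str] = {}
    de: set[str] = set()

    cursor = 0
    module_rows: dict[str, np.ndarray] = {}
    for mod in design.modules:
        rows = np.arange(cursor, cursor + mod.size)
        cursor += mod.size
        module_rows[mod.name] = rows
        profiles[mod.name] = mod.profile
        log2_shift[rows] = _profile_log2_shift(mod.profile, mod.log2_effect, k)
        for r in rows:
            labels[transcripts[r]] = mod.name
        if mod.profile != "null":
            de.update(transcripts[r] for r in rows)

    mu = baselines[:, None] * 2.0 ** log2_shift[:, group_of_sample]

    # shared latent factor per (module, sample) induces within-module correlation
    for mod in design.modules:
        w = mod.within_correlation
        if w == 0:
            continue
        f = rng.standard_normal(S)
        mu[module_rows[mod.name]] *= np.exp(w * f - 0.5 * w * w)[None, :]

    if design.batch_log2_effect:
        batch_codes = pd.Categorical(meta["batch"]).codes
        wobble = rng.standard_normal(len(set(batch_codes)))
        mu *= 2.0 ** (design.batch_log2_effect * wobble[batch_codes])[None, :]

    alpha = max(design.dispersion, 1e-12)
    if alpha < 1e-6:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / alpha
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)

    counts_df = pd.DataFrame(counts, index=pd.Index(transcripts, name="transcript"), columns=samples)
    truth = GroundTruth(module_labels=labels, module_profiles=profiles, de_transcripts=de)
    return counts_df, meta, truth


# ---------------------------------------------------------------------------
# annotations


def simulate_annotations(
    truth: GroundTruth,
    n_terms: int = 60,
    noise_rate: float = 0.1,
    planted_per_module: int = 2,
    planted_term_size: int = 20,
    background_term_size: int = 15,
    seed: int = 0,
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Plant GO-style annotation sets on top of the simulated transcripts.

    Each non-null planted module receives ``planted_per_module`` terms whose
    genes are drawn from the module with a ``noise_rate`` fraction replaced
    by uniform background genes (capped so planted terms stay >= 70% inside
    their module).  Remaining terms are uniform background.  Every term gets
    one process category: planted terms inherit their profile's category,
    background terms fall in the "other" bucket.
    """
    if not (0.0 <= noise_rate <= 1.0):
        raise ValueError("noise_rate must lie in [0, 1]")
    modules = [m for m, p in truth.module_profiles.items() if p != "null"]
    if n_terms < len(modules):
        raise ValueError(f"need at least {len(modules)} terms for {len(modules)} planted modules")

    rng = np.random.default_rng(seed)
    universe = sorted(truth.module_labels)
    by_module: dict[str, list[str]] = {}
    for t, m in truth.module_labels.items():
        by_module.setdefault(m, []).append(t)

    term_map: dict[str, set[str]] = {}
    category_map: dict[str, str] = {}
    planted_terms: dict[str, str] = {}
    idx = 0
    eff_noise = min(noise_rate, 0.3)
    for mod in modules:
        pool = sorted(by_module[mod])
        for _ in range(planted_per_module):
            term = f"GO:{idx:07d}"
            idx += 1
            n_in = max(3, int(round(planted_term_size * (1 - eff_noise))))
            n_in = min(n_in, len(pool))
            n_out = planted_term_size - n_in
            genes = set(rng.choice(pool, size=n_in, replace=False))
            if n_out > 0:
                genes |= set(rng.choice(universe, size=n_out, replace=False))
            term_map[term] = genes
            category_map[term] = CATEGORY_BY_PROFILE.get(
                truth.module_profiles[mod], BACKGROUND_CATEGORY
            )
            planted_terms[term] = mod
    while idx < n_terms:
        term = f"GO:{idx:07d}"
        idx += 1
        size = max(3, background_term_size)
        term_map[term] = set(rng.choice(universe, size=size, replace=False))
        category_map[term] = BACKGROUND_CATEGORY

    truth.term_map = term_map
    truth.category_map = category_map
    truth.planted_terms = planted_terms
    return term_map, category_map


# ---------------------------------------------------------------------------
# TF target sets and the PPI graph


def simulate_tf_and_ppi(
    truth: GroundTruth,
    n_tfs: int = 15,
    n_driven: int = 5,
    n_background_nodes: int = 150,
    targets_per_tf: int = 60,
    driven_de_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[dict[str, set[str]], InteractionGraph]:
    """Plant TF target sets and a PPI graph with an upstream hub.

    ``n_driven`` TFs draw ``driven_de_fraction`` of their targets from the
    planted differential transcripts; the rest of the TFs draw uniformly.
    The graph wires a hub node to every driven TF through two mediator
    nodes (hub -> mediator -> TF, confidences 0.95 / 0.9), attaches each
    driven TF to a dozen of its differential targets, and adds random
    low-confidence background edges.
    """
    if n_tfs < 5:
        raise ValueError("need n_tfs >= 5")
    if not (0 < n_driven <= n_tfs):
        raise ValueError("n_driven must lie in [1, n_tfs]")
    rng = np.random.default_rng(seed)
    universe = sorted(truth.module_labels)
    de = sorted(truth.de_transcripts)
    non_de = sorted(set(universe) - truth.de_transcripts)

    tf_targets: dict[str, set[str]] = {}
    driven = [f"TF{i:02d}" for i in range(1, n_driven + 1)]
    background_tfs = [f"TF{i:02d}" for i in range(n_driven + 1, n_tfs + 1)]
    for tf in driven:
        n_in = int(round(targets_per_tf * driven_de_fraction))
        n_in = min(n_in, len(de))
        genes = set(rng.choice(de, size=n_in, replace=False))
        genes |= set(rng.choice(non_de, size=targets_per_tf - n_in, replace=False))
        tf_targets[tf] = genes
    for tf in background_tfs:
        tf_targets[tf] = set(rng.choice(universe, size=targets_per_tf, replace=False))

    hub = "HUB_CYTOKINE"
    mediators = ["MED1", "MED2"]
    edges: list[tuple[str, str, float]] = []
    for med in mediators:
        edges.append((hub, med, 0.95))
    for i, tf in enumerate(driven):
        edges.append((mediators[i % len(mediators)], tf, 0.9))

    # driven TFs connect to a handful of differential targets; when GO
    # annotations were planted first, the wiring concentrates on annotated
    # (planted-term) genes so that grown networks carry a recoverable GO
    # signature, mirroring the dense annotation of curated PPI databases
    planted_genes = set()
    for term, mod in truth.planted_terms.items():
        planted_genes |= truth.term_map[term] & truth.de_transcripts
    for tf in driven:
        pool = sorted(planted_genes) if planted_genes else sorted(tf_targets[tf] & truth.de_transcripts)
        picked = rng.choice(pool, size=min(15, len(pool)), replace=False)
        for g in picked:
            if not any(frozenset((tf, g)) == frozenset(e[:2]) for e in edges):
                edges.append((tf, str(g), float(rng.uniform(0.6, 0.8))))

    # background: random gene nodes with sparse low-confidence edges
    bg_nodes = list(rng.choice(universe, size=min(n_background_nodes, len(universe)), replace=False))
    all_nodes = sorted({u for e in edges for u in e[:2]} | set(bg_nodes) | set(background_tfs))
    n_random_edges = 3 * len(bg_nodes)
    seen = {frozenset((u, v)) for u, v, _ in edges}
    attempts = 0
    while n_random_edges > 0 and attempts < 50 * n_random_edges:
        attempts += 1
        u, v = rng.choice(all_nodes, size=2, replace=False)
        key = frozenset((u, v))
        if key in seen:
            continue
        seen.add(key)
        edges.append((str(u), str(v), float(rng.uniform(0.1, 0.5))))
        n_random_edges -= 1

    graph = InteractionGraph.from_edges(edges)
    truth.tf_targets = tf_targets
    truth.driven_tfs = driven
    truth.hub_node = hub
    truth.cascade = [hub, *mediators, *driven]
    return tf_targets, graph


# ---------------------------------------------------------------------------
# one-call bundle + disk writer


@dataclass
class SimulatedStudy:
    counts: pd.DataFrame
    meta: pd.DataFrame
    term_map: dict[str, set[str]]
    category_map: dict[str, str]
    tf_targets: dict[str, set[str]]
    graph: InteractionGraph
    truth: GroundTruth


def simulate_study(design: SimulationDesign | None = None, seed: int = 0, **kwargs) -> SimulatedStudy:
    """Generate the full input bundle (counts, annotations, TF sets, PPI)."""
    if design is None:
        design = default_design(seed=seed)
    counts, meta, truth = simulate_counts(design)
    term_map, category_map = simulate_annotations(truth, seed=design.seed + 1, **kwargs)
    tf_targets, graph = simulate_tf_and_ppi(truth, seed=design.seed + 2)
    return SimulatedStudy(counts, meta, term_map, category_map, tf_targets, graph, truth)


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rio.write_counts_tsv(study.counts, out / "counts.tsv")
    rio.write_metadata(study.meta, out / "metadata.tsv")
    rio.write_gmt(study.term_map, out / "go_terms.gmt")
    rio.write_category_map(study.category_map, out / "go_categories.tsv")
    rio.write_gmt(study.tf_targets, out / "tf_targets.gmt")
    rio.write_edge_list(study.graph.edge_list(), out / "ppi_edges.tsv")
    study.truth.to_json(out / "truth.json")
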