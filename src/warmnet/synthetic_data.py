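"""Synthetic warming-experiment generator with known ground truth.

Emulates the post-bioinformatics outputs of a randomized-block infrared
warming experiment: relative-abundance tables for nematode and protist
communities (plus the pooled whole-microfauna table), per-sample metadata
(block, warming offset, depth layer), and 13 soil-property variables.

Inter-taxon rank correlation is planted through a Gaussian copula: each
module contributes one latent factor, member loadings are ``sqrt(r)`` where
``r = 2 sin(pi * rho_s / 6)`` converts the target Spearman ``rho_s`` to the
latent Pearson correlation. Negative-sign modules split their members into
two anti-correlated halves (sign-alternating loadings), the strongest
pairwise-negative structure that stays positive semidefinite for more than
two members. Marginals are log-normal (latent values exponentiated), a
monotone map that leaves Spearman targets untouched, then closed to
relative abundances per sample.

Treatment responses are parameterized on the warming-offset axis
(0, 0.8, 1.5, 3.0, 4.2 degC): each soil variable, functional group and
(optionally) module carries a :class:`ResponseCurve` with intercept, linear
and quadratic terms plus block random intercepts and residual noise. A
quadratic with a negative second-order coefficient yields the hump-shaped
mean response used throughout the defaults.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import AbundanceTable, NEMATODE_GROUPS, PROTIST_GROUPS

logger = logging.getLogger(__name__)

TREATMENTS = (0.0, 0.8, 1.5, 3.0, 4.2)
DEPTH_LAYERS = ("0-10cm", "10-20cm")

SOIL_VARIABLES = (
    "SM", "ST", "SOC", "DOC", "MBC", "MBN", "MBP",
    "pH", "TN", "TP", "AP", "NH4-N", "NO3-N",
)

#: carbon / nitrogen / phosphorus pools entering the multinutrient index
NUTRIENT_VARIABLES = (
    "SOC", "TN", "TP", "AP", "NH4-N", "NO3-N", "DOC", "MBC", "MBN", "MBP",
)


def spearman_to_latent_pearson(rho_s: float) -> float:
    """Pearson correlation of the latent normals that yields Spearman ``rho_s``."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass(frozen=True)
class DesignSpec:
    """Randomized block design: every treatment once per block, per layer."""

    n_blocks: int = 4
    treatments: tuple[float, ...] = TREATMENTS
    depth_layers: tuple[str, ...] = DEPTH_LAYERS
    n_nematode_taxa: int = 40
    n_protist_taxa: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValueError("need at least 2 blocks")
        if len(set(self.treatments)) != len(self.treatments):
            raise ValueError("treatments must be distinct")
        if 0.0 not in self.treatments:
            raise ValueError("treatments must include the 0.0 (ambient) control")
        if self.n_nematode_taxa < 1 or self.n_protist_taxa < 1:
            raise ValueError("taxon counts must be positive")

    @property
    def n_samples_per_layer(self) -> int:
        return self.n_blocks * len(self.treatments)


@dataclass(frozen=True)
class ModuleSpec:
    """Planted correlation module.

    ``within_module_correlation`` is the target Spearman magnitude between
    members. ``sign`` is "positive" (all pairs positive) or "negative"
    (members split into two anti-correlated halves: within-half pairs
    positive, cross-half pairs negative). ``latent_scale`` multiplies the
    member latent variables; it does not change planted correlations but
    widens the log-abundance spread of module taxa.
    """

    member_taxa: tuple[int, ...]
    within_module_correlation: float
    sign: str = "positive"
    latent_scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.member_taxa) < 2:
            raise ValueError("a module needs at least 2 member taxa")
        if len(set(self.member_taxa)) != len(self.member_taxa):
            raise ValueError("module members must be distinct")
        if not 0.0 <= abs(self.within_module_correlation) <= 1.0:
            raise ValueError("|within_module_correlation| must be <= 1")
        if self.sign not in ("positive", "negative"):
            raise ValueError("sign must be 'positive' or 'negative'")
        if self.latent_scale <= 0:
            raise ValueError("latent_scale must be positive")

    def loadings(self) -> np.ndarray:
        """Factor loadings (+/- sqrt(latent r)) per member, in member order."""
        r = spearman_to_latent_pearson(abs(self.within_module_correlation))
        lam = math.sqrt(r)
        out = np.full(len(self.member_taxa), lam)
        if self.sign == "negative":
            half = len(self.member_taxa) // 2
            out[half:] *= -1.0
        return out

    def planted_sign(self, i: int, j: int) -> int:
        """Planted correlation sign between members at positions i, j."""
        lo = self.loadings()
        return int(np.sign(lo[i] * lo[j]))


@dataclass(frozen=True)
class ResponseCurve:
    """Mean response over the warming-offset axis with block/residual noise.

    mean(T) = intercept + linear * T + quadratic * T**2. ``block_sd`` is the
    standard deviation of block random intercepts, ``noise_sd`` of residual
    noise. ``shape`` is a declaration checked against the coefficients.
    """

    shape: str = "flat"
    intercept: float = 0.0
    linear: float = 0.0
    quadratic: float = 0.0
    noise_sd: float = 0.0
    block_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.block_sd < 0:
            raise ValueError("noise_sd and block_sd must be >= 0")
        if self.shape not in ("flat", "linear", "quadratic"):
            raise ValueError("shape must be flat, linear or quadratic")
        if self.shape == "flat" and (self.linear != 0 or self.quadratic != 0):
            raise ValueError("flat curve must have zero treatment coefficients")
        if self.shape == "linear" and self.quadratic != 0:
            raise ValueError("linear curve must have zero quadratic coefficient")

    def mean(self, warming: np.ndarray | float) -> np.ndarray | float:
        w = np.asarray(warming, dtype=float)
        return self.intercept + self.linear * w + self.quadratic * w**2

    def attenuated(self, factor: float) -> "ResponseCurve":
        """Curve with treatment coefficients scaled by ``factor`` (depth effect)."""
        return replace(self, linear=self.linear * factor,
                       quadratic=self.quadratic * factor)


@dataclass
class Truth:
    """Everything needed to recompute expected means of generated variables."""

    spec: DesignSpec
    modules: dict[str, tuple[ModuleSpec, ...]]
    curves: dict[str, ResponseCurve]
    detection_limit: float
    subsoil_attenuation: float

    def expected_mean(self, variable: str, warming, depth: str) -> np.ndarray:
        curve = self.curves[variable]
        if depth != self.spec.depth_layers[0]:
            curve = curve.attenuated(self.subsoil_attenuation)
        return curve.mean(np.asarray(warming, dtype=float))


@dataclass
class SyntheticDataset:
    """A complete synthetic experiment with its generating truth."""

    tables: dict[str, AbundanceTable]
    metadata: pd.DataFrame
    soil: pd.DataFrame
    truth: Truth

    @property
    def sample_ids(self) -> pd.Index:
        return self.metadata.index

    def samples_in_layer(self, depth: str) -> pd.Index:
        return self.metadata.index[self.metadata["depth"] == depth]

    def functional_group_abundance(self, community: str) -> pd.DataFrame:
        """Per-sample relative abundance of each functional group (samples x groups)."""
        table = self.tables[community]
        groups = table.annotation["functional_group"]
        out = table.data.groupby(groups).sum().T
        out.index.name = "sample_id"
        return out

    def write_tsv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_tsv(outdir / f"abundance_{name}.tsv")
        self.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index_label="sample_id")
        self.soil.to_csv(outdir / "soil.tsv", sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# latent correlation machinery


def _validate_modules(n_taxa: int, modules: Sequence[ModuleSpec]) -> None:
    seen: set[int] = set()
    for m in modules:
        members = set(m.member_taxa)
        if not members <= set(range(n_taxa)):
            raise ValueError(f"module members {sorted(members)} outside [0, {n_taxa})")
        if members & seen:
            raise ValueError(
                f"module member sets overlap on taxa {sorted(members & seen)}"
            )
        seen |= members


def _latent_matrix(
    n_taxa: int, n_samples: int, modules: Sequence[ModuleSpec], rng: np.random.Generator
) -> np.ndarray:
    """Latent standard-normal taxa x samples matrix with planted factors."""
    z = rng.standard_normal((n_taxa, n_samples))
    for m in modules:
        factor = rng.standard_normal(n_samples)
        lo = m.loadings()
        idio = np.sqrt(np.clip(1.0 - lo**2, 0.0, None))
        for pos, taxon in enumerate(m.member_taxa):
            z[taxon] = m.latent_scale * (lo[pos] * factor + idio[pos] * z[taxon])
    return z


def correlated_abundances(
    n_taxa: int,
    n_samples: int,
    modules: Sequence[ModuleSpec] = (),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Non-negative taxa x samples matrix with planted Spearman structure.

    Correlation is induced on the latent Gaussian scale and carried through
    the (monotone) exponential marginal, so Spearman targets hold regardless
    of the heavy-tailed marginal shape.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3 for Spearman correlation to be useful")
    _validate_modules(n_taxa, modules)
    if rng is None:
        rng = np.random.default_rng(seed)
    return np.exp(_latent_matrix(n_taxa, n_samples, modules, rng))


# ---------------------------------------------------------------------------
# default study conditions


def default_modules(spec: DesignSpec) -> dict[str, tuple[ModuleSpec, ...]]:
    """Planted module structure emulating warming-responsive guilds.

    Per community: a strongly correlated module whose abundance follows a
    hump-shaped warming response (drives per-sample network complexity), a
    weakly correlated module abundant at ambient conditions and suppressed
    toward +3.0 degC (its correlations sit below network thresholds, so it
    moves cohesion but not edges), and a static anti-correlated guild pair
    providing negative edges.
    """
    nn, np_ = spec.n_nematode_taxa, spec.n_protist_taxa
    if nn < 40 or np_ < 40:
        raise ValueError("default module layout expects >= 40 taxa per community")
    # nematode group slices (40 taxa): bacterivore 0-7, fungivore 8-15,
    # herbivore 16-23, predator 24-31, omnivore 32-39
    nem = (
        # thermophilic omnivores: counter-guild anti-correlated (via
        # opposite treatment trends) with the ephemeral cool-adapted taxa;
        # net-negative connectedness with a mass peak at +3.0 degC drives
        # the NPC stability hump
        ModuleSpec(tuple(range(36, 40)), 0.0, latent_scale=0.4),
        # fungivore seesaw: static anti-correlated cliques (negative edges)
        ModuleSpec(tuple(range(8, 16)), 0.9, sign="negative"),
        # bacterivore + predator/omnivore consortium: one large static
        # clique that keeps the persistent network core dense
        ModuleSpec(tuple(range(0, 8)) + tuple(range(28, 36)), 0.9),
    )
    # protist group slices (40 taxa): consumer 0-12, parasite 13-25,
    # phototroph 26-39
    pro = (
        # thermophilic phototroph counter-guild
        ModuleSpec(tuple(range(34, 38)), 0.0, latent_scale=0.4),
        # phototroph seesaw: static anti-correlated cliques
        ModuleSpec(tuple(range(26, 34)), 0.9, sign="negative"),
        # consumer consortium: one large static clique
        ModuleSpec(tuple(range(0, 13)), 0.9),
    )
    return {"nematode": nem, "protist": pro}


def default_curves() -> dict[str, ResponseCurve]:
    """Treatment-response curves for the default synthetic experiment.

    Abundance-multiplier curves are on the log scale; soil curves are in
    measurement units. Nutrient pools peak at +3.0 degC (hump), matching the
    qualitative topsoil patterns the design emulates.
    """
    curves: dict[str, ResponseCurve] = {}

    # --- module abundance multipliers (log scale) -------------------------
    # counter-guild: a small thermophilic clique whose mass share rises
    # from ~2% at ambient to ~35% at +3.0 degC and falls back at +4.2
    counter = ResponseCurve("quadratic", intercept=-1.97, linear=2.24,
                            quadratic=-0.39, noise_sd=0.5, block_sd=0.2)
    for comm in ("nematode", "protist"):
        curves[f"{comm}:module:0"] = counter

    # ephemeral detection-limited taxa: presence (not just mass) dips
    # around +3.0 degC and partially recovers at +4.2; the large per-taxon
    # noise keeps them mutually uncorrelated, so they shed nodes -- not
    # edges -- from per-sample subnetworks, peaking connectance at +3.0
    ephemeral = ResponseCurve("quadratic", intercept=0.04, linear=-4.98,
                              quadratic=0.89, noise_sd=2.0, block_sd=0.2)
    group_curves = {
        "nematode:bacterivore": ResponseCurve("linear", linear=-0.08,
                                              noise_sd=0.25, block_sd=0.15),
        "nematode:fungivore": ResponseCurve("linear", linear=0.08,
                                            noise_sd=0.25, block_sd=0.15),
        "nematode:herbivore": ephemeral,
        "nematode:predator": ephemeral,  # taxa 24-31; 28-31 rarely detected anyway
        "nematode:omnivore": ResponseCurve("linear", linear=0.08,
                                           noise_sd=0.25, block_sd=0.15),
        "protist:consumer": ResponseCurve("linear", linear=-0.08,
                                          noise_sd=0.25, block_sd=0.15),
        "protist:parasite": ephemeral,
        "protist:phototroph": ResponseCurve("linear", linear=0.08,
                                            noise_sd=0.25, block_sd=0.15),
    }
    curves.update(group_curves)

    # --- soil properties (measurement units) ------------------------------
    curves["SM"] = ResponseCurve("linear", intercept=38.0, linear=-1.8,
                                 noise_sd=1.5, block_sd=1.0)
    curves["ST"] = ResponseCurve("linear", intercept=14.5, linear=0.9,
                                 noise_sd=0.3, block_sd=0.2)
    curves["pH"] = ResponseCurve("flat", intercept=4.6, noise_sd=0.15, block_sd=0.1)
    # nutrient pools: hump with vertex at +3.0 degC, peak ~2 residual sd
    nutrient_scale = {
        "SOC": (52.0, 4.0), "DOC": (310.0, 25.0), "MBC": (820.0, 60.0),
        "MBN": (95.0, 8.0), "MBP": (28.0, 2.5), "TN": (3.6, 0.3),
        "TP": (0.74, 0.06), "AP": (9.5, 0.8), "NH4-N": (11.0, 1.0),
        "NO3-N": (7.5, 0.7),
    }
    for var, (base, s) in nutrient_scale.items():
        a = 1.43 * s  # peak height (vertex 2.8 degC, quadratic=-a/5.6) ~2 s
        curves[var] = ResponseCurve("quadratic", intercept=base, linear=a,
                                    quadratic=-a / 5.6, noise_sd=s,
                                    block_sd=0.6 * s)
    return curves


# ---------------------------------------------------------------------------
# experiment generation


def _design_metadata(spec: DesignSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Sample metadata: every treatment exactly once per block, per layer."""
    rows = []
    for depth in spec.depth_layers:
        for block in range(1, spec.n_blocks + 1):
            order = rng.permutation(len(spec.treatments))
            for plot, ti in enumerate(order, start=1):
                t = spec.treatments[ti]
                sid = f"B{block}P{plot}_{depth}"
                rows.append((sid, block, t, depth))
    meta = pd.DataFrame(rows, columns=["sample_id", "block", "treatment", "depth"])
    return meta.set_index("sample_id")


def _curve_values(
    curve: ResponseCurve,
    meta: pd.DataFrame,
    topsoil: str,
    attenuation: float,
    rng: np.random.Generator,
    n_replicates: int = 1,
) -> np.ndarray:
    """Realized curve values per sample (optionally per replicate taxon).

    Treatment coefficients are attenuated below the topsoil; block random
    intercepts are shared across replicates (and layers), residual noise is
    drawn independently per replicate x sample.
    """
    warming = meta["treatment"].to_numpy(dtype=float)
    sub = meta["depth"].to_numpy() != topsoil
    mean_top = np.asarray(curve.mean(warming), dtype=float)
    mean_sub = np.asarray(curve.attenuated(attenuation).mean(warming), dtype=float)
    mean = np.where(sub, mean_sub, mean_top)
    blocks = meta["block"].to_numpy()
    block_levels = np.unique(blocks)
    block_eff = rng.normal(0.0, curve.block_sd, size=len(block_levels))
    block_map = dict(zip(block_levels, block_eff))
    mean = mean + np.array([block_map[b] for b in blocks])
    noise = rng.normal(0.0, curve.noise_sd, size=(n_replicates, len(meta)))
    return mean[None, :] + noise


def _community_table(
    community: str,
    n_taxa: int,
    groups: Sequence[str],
    modules: Sequence[ModuleSpec],
    curves: Mapping[str, ResponseCurve],
    meta: pd.DataFrame,
    spec: DesignSpec,
    detection_limit: float,
    attenuation: float,
    taxon_log_sd: float,
    rng: np.random.Generator,
) -> AbundanceTable:
    prefix = community[0].upper()
    taxa = [f"{prefix}{i:03d}" for i in range(n_taxa)]
    # round-robin-ish assignment: contiguous slices per functional group
    n_groups = len(groups)
    bounds = np.linspace(0, n_taxa, n_groups + 1).astype(int)
    group_of = np.empty(n_taxa, dtype=object)
    for gi, g in enumerate(groups):
        group_of[bounds[gi]:bounds[gi + 1]] = g

    z = _latent_matrix(n_taxa, len(meta), modules, rng)
    base = rng.normal(0.0, 1.0, size=n_taxa)
    log_abund = base[:, None] + taxon_log_sd * z

    for gi, g in enumerate(groups):
        key = f"{community}:{g}"
        if key not in curves:
            continue
        members = np.flatnonzero(group_of == g)
        vals = _curve_values(curves[key], meta, spec.depth_layers[0], attenuation,
                             rng, n_replicates=len(members))
        log_abund[members] += vals
    for mi, m in enumerate(modules):
        key = f"{community}:module:{mi}"
        if key not in curves:
            continue
        members = np.asarray(m.member_taxa)
        vals = _curve_values(curves[key], meta, spec.depth_layers[0], attenuation,
                             rng, n_replicates=len(members))
        log_abund[members] += vals

    abund = np.exp(log_abund)
    abund /= abund.sum(axis=0, keepdims=True)
    if detection_limit > 0:
        abund[abund < detection_limit] = 0.0
        abund /= abund.sum(axis=0, keepdims=True)

    data = pd.DataFrame(abund, index=taxa, columns=meta.index)
    annotation = pd.DataFrame(
        {"community": community, "functional_group": group_of}, index=taxa
    )
    return AbundanceTable(data, annotation)


def generate_experiment(
    spec: DesignSpec | None = None,
    modules: Mapping[str, Sequence[ModuleSpec]] | None = None,
    curves: Mapping[str, ResponseCurve] | None = None,
    detection_limit: float = 5e-4,
    subsoil_attenuation: float = 0.15,
    taxon_log_sd: float = 0.45,
) -> SyntheticDataset:
    """Generate a complete synthetic experiment (deterministic given seed).

    ``modules`` maps community -> planted :class:`ModuleSpec` list;
    ``curves`` maps variable names (soil variables, ``community:group`` and
    ``community:module:i`` abundance multipliers) to response curves.
    Defaults reproduce the package's standard study conditions: 4 blocks x
    5 warming levels x 2 depth layers, 40 nematode and 40 protist taxa,
    hump-shaped (peak +3.0 degC) responses for nutrient pools and the
    warming-responsive guild, treatment effects attenuated in the subsoil.
    """
    spec = spec or DesignSpec()
    modules = dict(modules) if modules is not None else default_modules(spec)
    curves = dict(curves) if curves is not None else default_curves()
    for comm, mods in modules.items():
        n = spec.n_nematode_taxa if comm == "nematode" else spec.n_protist_taxa
        _validate_modules(n, mods)

    # independent child streams: adding taxa to one community does not
    # perturb the other community, the soil table or the design
    root = np.random.SeedSequence(spec.seed)
    s_design, s_nema, s_prot, s_soil = root.spawn(4)
    meta = _design_metadata(spec, np.random.default_rng(s_design))

    tables: dict[str, AbundanceTable] = {}
    tables["nematode"] = _community_table(
        "nematode", spec.n_nematode_taxa, NEMATODE_GROUPS,
        modules.get("nematode", ()), curves, meta, spec,
        detection_limit, subsoil_attenuation, taxon_log_sd,
        np.random.default_rng(s_nema),
    )
    tables["protist"] = _community_table(
        "protist", spec.n_protist_taxa, PROTIST_GROUPS,
        modules.get("protist", ()), curves, meta, spec,
        detection_limit, subsoil_attenuation, taxon_log_sd,
        np.random.default_rng(s_prot),
    )
    whole_data = pd.concat(
        [0.5 * tables["nematode"].data, 0.5 * tables["protist"].data]
    )
    whole_ann = pd.concat(
        [tables["nematode"].annotation, tables["protist"].annotation]
    )
    tables["whole"] = AbundanceTable(whole_data, whole_ann)

    rng_soil = np.random.default_rng(s_soil)
    soil_cols = {}
    for var in SOIL_VARIABLES:
        if var not in curves:
            raise ValueError(f"no response curve provided for soil variable {var!r}")
        soil_cols[var] = _curve_values(
            curves[var], meta, spec.depth_layers[0], subsoil_attenuation, rng_soil
        )[0]
    soil = pd.DataFrame(soil_cols, index=meta.index)

    truth = Truth(spec=spec, modules={k: tuple(v) for k, v in modules.items()},
                  curves=curves, detection_limit=detection_limit,
                  subsoil_attenuation=subsoil_attenuation)
    return SyntheticDataset(tables=tables, metadata=meta, soil=soil, truth=truth)
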