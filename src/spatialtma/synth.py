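"""Synthetic multiplexed-TMA cohort generator with recoverable ground truth.

Generates point patterns on 1 mm-diameter discs (one per core) with
configurable cell-type mixtures, tumour nests, pairwise spatial attractions
(implemented by relocation-thinning so the planted effect is exactly
controllable), compositional hotspots, per-core batch intensity shifts,
lognormal marker noise and proportional-hazards survival times.

Every downstream stage of the pipeline has a planted target here: cell
typing recovers the signature mixture, compartments recover the nests,
proximity densities recover the attractions, neighbourhoods recover the
hotspots and survival models recover the hazard coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from spatialtma.config import DEFAULT_MARKERS, DEFAULT_SIGNATURES, TUMOUR_TYPES
from spatialtma.errors import ConfigurationError, GenerationError

# Baseline mixture (sums to 1); tumour subsets total 35%.
_DEFAULT_PROPORTIONS: dict[str, float] = {
    "Tumour HLADR": 0.13,
    "Tumour CD44": 0.12,
    "Tumour Ki67": 0.10,
    "Stroma": 0.12,
    "CD4 T cell": 0.08,
    "CD8 T cell": 0.07,
    "Macrophage": 0.06,
    "Monocyte": 0.05,
    "Treg": 0.04,
    "B cell": 0.04,
    "Blood vessel": 0.04,
    "Granulocyte": 0.03,
    "Lymphocyte": 0.03,
    "Mast cell": 0.02,
    "Proliferating lymphocyte": 0.02,
    "Effector CD4 T cell": 0.02,
    "CCR7 CD8 T cell": 0.015,
    "Lymphatic": 0.01,
    "Vessel lymphocyte": 0.005,
}


@dataclass
class CellTypeSpec:
    """One synthetic cell type: signature markers and per-group mixture weight."""

    name: str
    markers: tuple[str, ...]
    prop_r: float
    prop_nr: float


@dataclass
class NestSpec:
    """Tumour-nest geometry per core."""

    n_nests: int = 3
    radius_um: float = 120.0
    tumour_fraction: float = 0.9  # fraction of tumour cells placed inside nests


@dataclass
class AttractionSpec:
    """Pairwise attraction: each type-A cell attracts one type-B satellite
    with the group-specific probability (relocation-thinning)."""

    type_a: str
    type_b: str
    radius_um: float = 20.0
    strength_r: float = 0.0
    strength_nr: float = 0.0

    def strength(self, group: str) -> float:
        return self.strength_r if group == "R" else self.strength_nr


@dataclass
class HotspotSpec:
    """A compositional hotspot disc: listed types are relocated into it with
    per-group probability, optionally boosted per type."""

    radius_um: float = 150.0
    types: tuple[str, ...] = (
        "CD4 T cell", "CD8 T cell", "Monocyte", "Mast cell", "Treg",
    )
    fraction_r: float = 0.0
    fraction_nr: float = 0.0
    type_boost: dict = field(default_factory=dict)  # type -> (boost_r, boost_nr)

    def relocation_prob(self, cell_type: str, group: str) -> float:
        base = self.fraction_r if group == "R" else self.fraction_nr
        boost_r, boost_nr = self.type_boost.get(cell_type, (1.0, 1.0))
        return float(np.clip(base * (boost_r if group == "R" else boost_nr), 0, 1))


@dataclass
class SurvivalSpec:
    """Exponential proportional-hazards outcome model with independent censoring."""

    baseline_hazard: float = 1.0 / 1500.0  # events per day
    coefs: dict = field(default_factory=dict)  # feature name -> log hazard per SD
    censor_prob: float = 0.3
    max_followup_days: float = 3000.0


@dataclass
class SynthConfig:
    """Full parameterization of a synthetic cohort."""

    n_cores: int = 8
    cells_per_core: int = 2000
    frac_responders: float = 0.5
    cell_types: list[CellTypeSpec] = field(default_factory=list)
    nest_spec: NestSpec = field(default_factory=NestSpec)
    attractions: list[AttractionSpec] = field(default_factory=list)
    hotspot: HotspotSpec | None = None
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    core_radius_um: float = 500.0
    margin_distance_um: float = 30.0
    base_positive: float = 300.0
    base_negative: float = 10.0
    dapi_base: float = 200.0
    noise_sigma: float = 0.35
    batch_sigma: float = 0.25
    area_mean_um2: float = 45.0
    area_mean_tumour_um2: float = 70.0
    area_sigma: float = 0.2
    include_intensities: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cell_types:
            self.cell_types = default_cell_types()
        self.validate()

    def validate(self) -> None:
        if self.n_cores < 1 or self.cells_per_core < 1:
            raise ConfigurationError("n_cores and cells_per_core must be positive")
        if not 0.0 <= self.frac_responders <= 1.0:
            raise ConfigurationError("frac_responders must lie in [0, 1]")
        for group, props in (("R", self.proportions("R")), ("NR", self.proportions("NR"))):
            total = float(np.sum(list(props.values())))
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ConfigurationError(
                    f"{group} baseline proportions sum to {total:.6f}, expected 1"
                )
            if any(p < 0 for p in props.values()):
                raise ConfigurationError("proportions must be nonnegative")
        if self.nest_spec.radius_um <= 0:
            raise ConfigurationError("nest radius must be positive")
        if self.nest_spec.radius_um >= self.core_radius_um:
            raise ConfigurationError("nest radius must be smaller than the core radius")
        for att in self.attractions:
            if not (0 <= att.strength_r <= 1 and 0 <= att.strength_nr <= 1):
                raise ConfigurationError("attraction strengths must lie in [0, 1]")
            if att.radius_um <= 0:
                raise ConfigurationError("attraction radius must be positive")
        if self.survival.baseline_hazard < 0:
            raise ConfigurationError("baseline hazard must be nonnegative")
        # crude packing feasibility: >25 cells per 100 µm² is unphysical
        density = self.cells_per_core / (math.pi * self.core_radius_um**2)
        if density > 0.25:
            raise GenerationError(
                f"requested density {density:.3f} cells/µm² exceeds packing "
                f"feasibility (~0.25 cells/µm² at nuclear scale)"
            )

    def proportions(self, group: str) -> dict[str, float]:
        return {
            ct.name: (ct.prop_r if group == "R" else ct.prop_nr)
            for ct in self.cell_types
        }

    @property
    def type_names(self) -> list[str]:
        return [ct.name for ct in self.cell_types]


@dataclass
class GroundTruth:
    """Planted truth emitted alongside a synthetic cohort."""

    cells: pd.DataFrame  # cell_id, sample_id, true_type, true_compartment
    response: pd.Series  # sample_id -> "R"/"NR"
    features_true: pd.DataFrame  # per-sample true type proportions
    attractions: list[AttractionSpec]
    hotspot: HotspotSpec | None
    survival_coefs: dict


def default_cell_types(
    scale: dict | None = None,
) -> list[CellTypeSpec]:
    """The 19 default cell types with canonical signatures.

    Parameters
    ----------
    scale
        Optional ``{type name: (multiplier_r, multiplier_nr)}`` applied to the
        baseline proportion before renormalization (used to plant group
        abundance effects, e.g. ``{"Treg": (1.0, 2.0)}``).
    """
    scale = scale or {}
    props_r = dict(_DEFAULT_PROPORTIONS)
    props_nr = dict(_DEFAULT_PROPORTIONS)
    for name, (mr, mnr) in scale.items():
        if name not in props_r:
            raise ConfigurationError(f"unknown cell type {name!r} in scale")
        props_r[name] *= mr
        props_nr[name] *= mnr
    tot_r = sum(props_r.values())
    tot_nr = sum(props_nr.values())
    return [
        CellTypeSpec(
            name=name,
            markers=tuple(DEFAULT_SIGNATURES[name]),
            prop_r=props_r[name] / tot_r,
            prop_nr=props_nr[name] / tot_nr,
        )
        for name in _DEFAULT_PROPORTIONS
    ]


def _uniform_disc(rng: np.random.Generator, n: int, radius: float,
                  cx: float = 0.0, cy: float = 0.0) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def _point_near(rng: np.random.Generator, anchor: np.ndarray, radius: float,
                core_radius: float) -> np.ndarray:
    """Uniform point within `radius` of `anchor`, constrained to the core disc."""
    for _ in range(200):
        p = _uniform_disc(rng, 1, radius, anchor[0], anchor[1])[0]
        if p[0] ** 2 + p[1] ** 2 <= core_radius**2:
            return p
    return anchor.copy()  # anchor is inside the core; degenerate fallback


@dataclass
class CoreSpec:
    """Resolved per-core placement request handed to :func:`place_core`."""

    sample_id: str
    counts: dict  # type name -> cell count
    group: str  # "R" or "NR"
    nest_spec: NestSpec
    attractions: list[AttractionSpec]
    hotspot: HotspotSpec | None
    core_radius_um: float
    margin_distance_um: float
    tumour_types: tuple[str, ...] = TUMOUR_TYPES


def place_core(core_spec: CoreSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Place one core's cells; returns x_um, y_um, true_type, true_compartment.

    Tumour-typed cells are concentrated in nests; hotspot types are relocated
    into the hotspot disc; attraction satellites are placed last so planted
    proximities are exact.
    """
    R = core_spec.core_radius_um
    nest = core_spec.nest_spec
    if nest.radius_um >= R:
        raise GenerationError("nest centres cannot fit inside the core disc")

    types: list[str] = []
    for name, n in core_spec.counts.items():
        types.extend([name] * int(n))
    n_cells = len(types)
    if n_cells == 0:
        raise GenerationError("a core with zero cells was requested")
    type_arr = np.array(types)
    xy = _uniform_disc(rng, n_cells, R)

    nest_centres = _uniform_disc(rng, nest.n_nests, R - nest.radius_um)
    is_tumour = np.isin(type_arr, core_spec.tumour_types)
    in_nest = is_tumour & (rng.random(n_cells) < nest.tumour_fraction)
    idx_nest = np.flatnonzero(in_nest)
    if idx_nest.size:
        which = rng.integers(0, nest.n_nests, idx_nest.size)
        offsets = _uniform_disc(rng, idx_nest.size, nest.radius_um)
        xy[idx_nest] = nest_centres[which] + offsets

    hotspot = core_spec.hotspot
    hotspot_centre = None
    if hotspot is not None:
        hotspot_centre = _uniform_disc(rng, 1, max(R - hotspot.radius_um, 1.0))[0]
        for name in hotspot.types:
            p = hotspot.relocation_prob(name, core_spec.group)
            if p <= 0:
                continue
            idx = np.flatnonzero(type_arr == name)
            move = idx[rng.random(idx.size) < p]
            if move.size:
                xy[move] = hotspot_centre + _uniform_disc(
                    rng, move.size, hotspot.radius_um
                )

    for att in core_spec.attractions:
        strength = att.strength(core_spec.group)
        if strength <= 0:
            continue
        anchors = np.flatnonzero(type_arr == att.type_a)
        pool = list(np.flatnonzero(type_arr == att.type_b))
        rng.shuffle(pool)
        for a in anchors:
            if not pool:
                break
            if rng.random() < strength:
                b = pool.pop()
                xy[b] = _point_near(rng, xy[a], att.radius_um, R)

    d_nest = np.min(
        np.linalg.norm(xy[:, None, :] - nest_centres[None, :, :], axis=2), axis=1
    )
    compartment = np.where(
        d_nest <= nest.radius_um,
        "tumour",
        np.where(
            d_nest <= nest.radius_um + core_spec.margin_distance_um,
            "margin",
            "stroma",
        ),
    )
    return pd.DataFrame(
        {
            "sample_id": core_spec.sample_id,
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "true_type": type_arr,
            "true_compartment": compartment,
        }
    )


def _marker_intensities(
    cells: pd.DataFrame, config: SynthConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Signature-mean × per-core batch shift × lognormal noise, plus DAPI."""
    markers = list(DEFAULT_MARKERS)
    sig_lookup = {ct.name: set(ct.markers) for ct in config.cell_types}
    base = np.full((len(sig_lookup), len(markers)), config.base_negative)
    type_index = {name: i for i, name in enumerate(sig_lookup)}
    for name, sig in sig_lookup.items():
        for j, m in enumerate(markers):
            if m in sig:
                base[type_index[name], j] = config.base_positive

    rows = np.array([type_index[t] for t in cells["true_type"]])
    out = np.empty((len(cells), len(markers) + 1))
    for sample_id, idx in cells.groupby("sample_id", sort=False).indices.items():
        shift = np.exp(rng.normal(0.0, config.batch_sigma, len(markers) + 1))
        noise = np.exp(
            rng.normal(0.0, config.noise_sigma, (len(idx), len(markers) + 1))
        )
        out[idx, : len(markers)] = (
            base[rows[idx]] * shift[: len(markers)] * noise[:, : len(markers)]
        )
        out[idx, len(markers)] = config.dapi_base * shift[-1] * noise[:, -1]
    return pd.DataFrame(out, columns=markers + ["DAPI"], index=cells.index)


def simulate_outcomes(
    features_true: pd.DataFrame,
    survival_spec: SurvivalSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw exponential survival times with hazard = baseline × exp(Σ coef·z).

    Coefficients apply to z-scored feature columns. With ``censor_prob`` each
    subject is independently censored at a uniform fraction of its event time;
    follow-up is also capped at ``max_followup_days``.
    """
    if survival_spec.baseline_hazard < 0:
        raise ConfigurationError("baseline hazard must be nonnegative")
    n = len(features_true)
    log_hr = np.zeros(n)
    for feat, coef in survival_spec.coefs.items():
        if feat not in features_true.columns:
            raise ConfigurationError(f"survival coefficient on unknown feature {feat!r}")
        col = features_true[feat].to_numpy(dtype=float)
        sd = col.std(ddof=0)
        z = (col - col.mean()) / sd if sd > 0 else np.zeros(n)
        log_hr += coef * z
    hazard = survival_spec.baseline_hazard * np.exp(log_hr)
    with np.errstate(divide="ignore"):
        t_event = rng.exponential(1.0 / np.maximum(hazard, 1e-300))
    censored = rng.random(n) < survival_spec.censor_prob
    os_days = np.where(censored, rng.random(n) * t_event, t_event)
    event = (~censored).astype(int)
    over = os_days > survival_spec.max_followup_days
    os_days = np.where(over, survival_spec.max_followup_days, os_days)
    event = np.where(over, 0, event)
    os_days = np.maximum(os_days, 1e-6)  # os_days > 0 invariant
    return pd.DataFrame(
        {
            "sample_id": features_true.index,
            "os_days": os_days,
            "event": event,
        }
    ).reset_index(drop=True)


def _covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sex": rng.choice(["M", "F"], n),
            "stage": rng.choice(["I", "II", "III", "IV"], n),
            "histology": rng.choice(
                ["Adenocarcinoma", "Squamous Cell Carcinoma"], n, p=[0.7, 0.3]
            ),
            "agent": rng.choice(
                ["NIVOLUMAB", "PEMBROLIZUMAB", "DURVALUMAB"], n, p=[0.7, 0.25, 0.05]
            ),
        }
    )


def generate_cohort(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a full synthetic cohort.

    Returns
    -------
    cells
        One row per cell: cell_id, sample_id, x_um, y_um, nuclear_area_um2,
        one raw-intensity column per marker plus DAPI (unless
        ``include_intensities`` is off).
    clinical
        sample_id, response, os_days, event plus categorical covariates.
    truth
        :class:`GroundTruth` with per-cell true labels and planted effects.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_r = int(round(config.frac_responders * config.n_cores))
    groups = ["R"] * n_r + ["NR"] * (config.n_cores - n_r)
    sample_ids = [f"core{i:03d}" for i in range(config.n_cores)]

    per_core = []
    for sample_id, group in zip(sample_ids, groups):
        props = config.proportions(group)
        names = list(props)
        counts = rng.multinomial(config.cells_per_core, [props[n] for n in names])
        spec = CoreSpec(
            sample_id=sample_id,
            counts=dict(zip(names, counts)),
            group=group,
            nest_spec=config.nest_spec,
            attractions=config.attractions,
            hotspot=config.hotspot,
            core_radius_um=config.core_radius_um,
            margin_distance_um=config.margin_distance_um,
        )
        per_core.append(place_core(spec, rng))
    cells = pd.concat(per_core, ignore_index=True)
    cells.insert(0, "cell_id", [f"c{i:07d}" for i in range(len(cells))])

    is_tumour = cells["true_type"].isin(TUMOUR_TYPES).to_numpy()
    mean_area = np.where(is_tumour, config.area_mean_tumour_um2, config.area_mean_um2)
    cells["nuclear_area_um2"] = mean_area * np.exp(
        rng.normal(0.0, config.area_sigma, len(cells))
    )

    if config.include_intensities:
        intensities = _marker_intensities(cells, config, rng)
        cells = pd.concat([cells, intensities], axis=1)

    features_true = (
        cells.groupby("sample_id")["true_type"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=config.type_names, fill_value=0.0)
    )
    features_true.columns = [f"prop|{c}" for c in features_true.columns]
    features_true = features_true.loc[sample_ids]

    surv = simulate_outcomes(features_true, config.survival, rng)
    clinical = pd.DataFrame({"sample_id": sample_ids, "response": groups})
    clinical = clinical.merge(surv, on="sample_id")
    clinical = pd.concat([clinical, _covariates(config.n_cores, rng)], axis=1)

    truth = GroundTruth(
        cells=cells[["cell_id", "sample_id", "true_type", "true_compartment"]].copy(),
        response=pd.Series(groups, index=sample_ids, name="response"),
        features_true=features_true,
        attractions=list(config.attractions),
        hotspot=config.hotspot,
        survival_coefs=dict(config.survival.coefs),
    )
    return cells, clinical, truth
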