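"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generative model for participant ``p`` of group ``g`` and ROI ``i`` is

    v_pi = base_means[i] + marker_shift(g, i)
           + beta_age[i] * (age_p - mean_age)
           + beta_icv[i] * (icv_p - mean_icv)
           + (Lambda_g @ f_p)[i] + eps_pi

with latent factors ``f_p ~ N(0, diag(factor_sd^2))`` and independent noise
``eps_pi ~ N(0, noise_sd[i]^2)``.  Group-level covariance structure (what
the covariance networks detect) is planted through the per-group loading
matrices; volumetric marker effects are additive mean shifts that leave
the covariance untouched, so the two arms of the analysis can be probed
independently.

Shipped specifications:

* :func:`paperlike_spec` — a three-group cohort (131/67/235) over the full
  100-ROI catalog, with a seven-module block-factor structure in the
  control group, weaker/flatter structure in the patient groups, and
  pallidal/thalamic marker shifts (a bilateral trait/state pattern).
* :func:`tiny_spec` — 30/30/30 over a reduced 20-ROI catalog, for fast tests.
* :func:`null_pair_spec` — two groups drawn from one identical law, for
  calibration of the permutation machinery.
* :func:`contrast_pair_spec` — a two-group pair in which group 1 carries a
  less clustered, longer-pathed covariance structure than group 2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .catalog import default_catalog
from .io import GROUPS, ParticipantRecord, ROIVolumeTable

__all__ = [
    "FactorModel",
    "CohortSpec",
    "SpecError",
    "generate_cohort",
    "null_pair",
    "paperlike_spec",
    "tiny_spec",
    "null_pair_spec",
    "contrast_pair_spec",
]


class SpecError(ValueError):
    """Raised when a cohort specification is internally inconsistent."""


@dataclass(frozen=True)
class FactorModel:
    """Per-group latent-factor model: loadings (p x k) and factor sds (k,)."""

    loadings: np.ndarray
    factor_sd: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "loadings", np.atleast_2d(np.asarray(self.loadings, float)))
        object.__setattr__(self, "factor_sd", np.atleast_1d(np.asarray(self.factor_sd, float)))
        if self.loadings.shape[1] != self.factor_sd.shape[0]:
            raise SpecError("factor_sd length must equal the number of loading columns")

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def implied_cov(self, noise_sd: np.ndarray) -> np.ndarray:
        """Population covariance Lambda diag(sd^2) Lambda' + diag(noise_sd^2)."""
        lam = self.loadings * self.factor_sd
        return lam @ lam.T + np.diag(np.asarray(noise_sd, float) ** 2)


@dataclass
class CohortSpec:
    """Everything needed to draw a cohort; fully reproducible from ``seed``."""

    roi_names: list[str]
    n_per_group: dict[str, int]
    age_distribution: dict[str, tuple[float, float]]
    icv_distribution: tuple[float, float]
    base_means: np.ndarray
    beta_age: np.ndarray
    beta_icv: np.ndarray
    noise_sd: np.ndarray
    factor_model: dict[str, FactorModel]
    marker_effects: list[tuple[str, str, float]] = field(default_factory=list)
    gender_male_fraction: dict[str, float] = field(default_factory=dict)
    clinical: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        p = len(self.roi_names)
        for name in ("base_means", "beta_age", "beta_icv", "noise_sd"):
            arr = np.broadcast_to(np.asarray(getattr(self, name), float), (p,)).copy()
            setattr(self, name, arr)
        if not np.all(self.noise_sd > 0):
            raise SpecError("noise_sd must be positive for every ROI")
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise SpecError(f"unknown group label {g!r}")
            if n <= 2:
                raise SpecError(f"group {g}: need more than 2 participants")
            if g not in self.factor_model:
                raise SpecError(f"group {g}: no factor model")
            if self.factor_model[g].loadings.shape[0] != p:
                raise SpecError(
                    f"group {g}: loading matrix has "
                    f"{self.factor_model[g].loadings.shape[0]} rows, expected {p}"
                )
        for roi, g, _ in self.marker_effects:
            if roi not in self.roi_names:
                raise SpecError(f"marker effect on unknown ROI {roi!r}")
            if g not in self.n_per_group:
                raise SpecError(f"marker effect on unknown group {g!r}")

    @property
    def groups(self) -> list[str]:
        return [g for g in GROUPS if g in self.n_per_group]

    def is_null(self, group_a: str, group_b: str) -> bool:
        """True when the two groups share one generative law exactly."""
        fa, fb = self.factor_model[group_a], self.factor_model[group_b]
        same_factors = (
            fa.loadings.shape == fb.loadings.shape
            and np.array_equal(fa.loadings, fb.loadings)
            and np.array_equal(fa.factor_sd, fb.factor_sd)
        )
        no_markers = not any(g in (group_a, group_b) and s != 0 for _, g, s in self.marker_effects)
        same_age = self.age_distribution.get(group_a) == self.age_distribution.get(group_b)
        return same_factors and no_markers and same_age

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for name in ("base_means", "beta_age", "beta_icv", "noise_sd"):
            d[name] = getattr(self, name).tolist()
        d["factor_model"] = {
            g: {"loadings": fm.loadings.tolist(), "factor_sd": fm.factor_sd.tolist()}
            for g, fm in self.factor_model.items()
        }
        d["marker_effects"] = [[r, g, float(s)] for r, g, s in self.marker_effects]
        d["age_distribution"] = {
            g: [float(a), float(b)] for g, (a, b) in self.age_distribution.items()
        }
        d["icv_distribution"] = [float(v) for v in self.icv_distribution]
        d["clinical"] = {
            g: {k: [float(x) for x in v] for k, v in per.items()}
            for g, per in self.clinical.items()
        }
        d["gender_male_fraction"] = {
            g: float(v) for g, v in self.gender_male_fraction.items()
        }
        d["n_per_group"] = {g: int(n) for g, n in self.n_per_group.items()}
        d["seed"] = int(self.seed)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["factor_model"] = {
            g: FactorModel(np.asarray(fm["loadings"]), np.asarray(fm["factor_sd"]))
            for g, fm in d["factor_model"].items()
        }
        d["marker_effects"] = [tuple(m) for m in d.get("marker_effects", [])]
        d["age_distribution"] = {g: tuple(v) for g, v in d["age_distribution"].items()}
        d["icv_distribution"] = tuple(d["icv_distribution"])
        d["clinical"] = {
            g: {k: tuple(v) for k, v in per.items()} for g, per in d.get("clinical", {}).items()
        }
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# generation


def _pop_age_mean(spec: CohortSpec) -> float:
    w = np.array([spec.n_per_group[g] for g in spec.groups], float)
    m = np.array([spec.age_distribution[g][0] for g in spec.groups], float)
    return float(np.average(m, weights=w))


def generate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[list[ParticipantRecord], ROIVolumeTable]:
    """Draw one cohort from ``spec``; identical output for identical seeds."""
    rng = substream(spec.seed if seed is None else seed, "cohort")
    p = len(spec.roi_names)
    mean_age = _pop_age_mean(spec)
    mean_icv = spec.icv_distribution[0]

    shift = {g: np.zeros(p) for g in spec.groups}
    roi_index = {r: i for i, r in enumerate(spec.roi_names)}
    for roi, g, delta in spec.marker_effects:
        if g in shift:
            shift[g][roi_index[roi]] += delta

    records: list[ParticipantRecord] = []
    blocks: list[np.ndarray] = []
    ids: list[str] = []
    for g in spec.groups:
        n = spec.n_per_group[g]
        a_mean, a_sd = spec.age_distribution[g]
        ages = np.clip(rng.normal(a_mean, a_sd, n), 18.0, None)
        icvs = rng.normal(mean_icv, spec.icv_distribution[1], n)
        male = rng.random(n) < spec.gender_male_fraction.get(g, 0.5)
        clin = spec.clinical.get(g, {})

        def draw(field_name: str, lo: float | None = 0.0):
            if field_name not in clin:
                return [None] * n
            mu, sd = clin[field_name]
            vals = rng.normal(mu, sd, n)
            if lo is not None:
                vals = np.clip(vals, lo, None)
            return vals

        edu = draw("education", lo=6.0)
        hamd = draw("hamd17")
        rrs = draw("rrs")
        dur = draw("illness_duration", lo=0.5)
        rem = draw("illness_remission", lo=0.5)

        fm = spec.factor_model[g]
        f = rng.normal(0.0, 1.0, (n, fm.n_factors)) * fm.factor_sd
        eps = rng.normal(0.0, 1.0, (n, p)) * spec.noise_sd
        vols = (
            spec.base_means
            + shift[g]
            + np.outer(ages - mean_age, spec.beta_age)
            + np.outer(icvs - mean_icv, spec.beta_icv)
            + f @ fm.loadings.T
            + eps
        )
        blocks.append(vols)
        for i in range(n):
            pid = f"{g}{i:04d}"
            ids.append(pid)
            records.append(
                ParticipantRecord(
                    id=pid,
                    group=g,
                    gender="male" if male[i] else "female",
                    age=float(ages[i]),
                    icv=float(icvs[i]),
                    education=None if edu[i] is None else float(edu[i]),
                    hamd17=None if hamd[i] is None else float(round(hamd[i])),
                    rrs=None if rrs[i] is None else float(round(rrs[i])),
                    illness_duration=None if dur[i] is None else float(dur[i]),
                    illness_remission=None if rem[i] is None else float(rem[i]),
                )
            )

    volumes = pd.DataFrame(
        np.vstack(blocks), index=pd.Index(ids, name="id"), columns=spec.roi_names
    )
    return records, ROIVolumeTable.from_records(records, volumes)


def null_pair(
    spec: CohortSpec, groups: tuple[str, str], seed: int | None = None
) -> tuple[list[ParticipantRecord], ROIVolumeTable]:
    """Draw the two named groups from a spec that treats them identically."""
    if not spec.is_null(*groups):
        raise SpecError(f"spec is not null for groups {groups}")
    records, table = generate_cohort(spec, seed=seed)
    keep = [r for r in records if r.group in groups]
    return keep, table.select_groups(groups)


# ---------------------------------------------------------------------------
# shipped specifications

#: typical FreeSurfer volumes (mm^3) per structure, used as base means
_BASE_MEANS = {
    "Caudate": 3600.0, "Putamen": 4900.0, "Accumbens-area": 620.0, "Pallidum": 1820.0,
    "Lateral-nucleus": 700.0, "Basal-nucleus": 450.0, "Accessory-Basal-nucleus": 280.0,
    "Anterior-amygdaloid-area": 60.0, "Central-nucleus": 50.0, "Medial-nucleus": 25.0,
    "Cortical-nucleus": 28.0, "Corticoamygdaloid-transition": 170.0,
    "Paralaminar-nucleus": 52.0,
    "Hippocampal-tail": 550.0, "Subiculum": 440.0, "Presubiculum": 310.0,
    "Parasubiculum": 65.0, "CA1": 640.0, "CA2": 25.0, "CA3": 200.0, "CA4": 250.0,
    "GC-ML-DG": 290.0, "Molecular-layer-HP": 560.0, "Fimbria": 90.0, "HATA": 60.0,
    "AV": 130.0, "LD": 30.0, "LP": 120.0, "VA": 400.0, "VAmc": 30.0, "VLa": 670.0,
    "VLp": 860.0, "VPL": 830.0, "VM": 21.0, "CeM": 60.0, "CL": 35.0, "CM": 250.0,
    "Pc": 4.0, "Pf": 55.0, "Pt": 7.0, "MV-Re": 12.0, "MDm": 680.0, "MDl": 260.0,
    "LGN": 120.0, "MGN": 110.0, "L-Sg": 25.0, "PuA": 220.0, "PuM": 1000.0,
    "PuI": 230.0, "PuL": 170.0,
}

#: marker shifts (mm^3): pallidal/left-PuA deficits in both patient groups
#: (trait pattern), right pallidum + right ventral-lateral deficits in the
#: remitted group only (state pattern)
_PAPERLIKE_MARKERS = [
    ("L_Pallidum", "cMDD", -126.0),
    ("L_Pallidum", "RD", -164.0),
    ("L_PuA", "cMDD", -3.9),
    ("L_PuA", "RD", -4.3),
    ("R_Pallidum", "RD", -133.0),
    ("R_VLa", "RD", -10.8),
    ("R_VLp", "RD", -10.2),
]

_CLINICAL = {
    "cMDD": {
        "education": (14.00, 2.22), "hamd17": (22.45, 4.88), "rrs": (58.29, 11.14),
        "illness_duration": (9.46, 12.13),
    },
    "RD": {
        "education": (14.52, 2.22), "hamd17": (3.72, 2.93), "rrs": (44.84, 10.19),
        "illness_duration": (13.77, 8.98), "illness_remission": (5.56, 3.63),
    },
    "HC": {
        "education": (14.25, 0.82), "hamd17": (2.12, 2.31), "rrs": (43.95, 8.76),
    },
}

_AGES = {"cMDD": (21.77, 4.01), "RD": (21.70, 3.77), "HC": (21.35, 2.91)}
_MALE_FRACTION = {"cMDD": 59 / 131, "RD": 29 / 67, "HC": 113 / 235}
_ICV = (1.45e6, 1.3e5)


def _base_vector(roi_names: list[str]) -> np.ndarray:
    return np.array([_BASE_MEANS[r.split("_", 1)[1]] for r in roi_names])


def _seven_module_blocks(roi_names: list[str]) -> list[list[int]]:
    """Anatomical 7-module partition: bilateral basal ganglia, then
    amygdala / hippocampus / thalamus per hemisphere."""
    cat = default_catalog()
    blocks: dict[str, list[int]] = {}
    for i, roi in enumerate(roi_names):
        group = cat.structure_group(roi)
        hemi = cat.hemisphere(roi)
        key = "basal_ganglia" if group == "basal_ganglia" else f"{hemi}_{group}"
        blocks.setdefault(key, []).append(i)
    return list(blocks.values())


def _normalized_model(lam_rel: np.ndarray, total_sd: np.ndarray) -> tuple[FactorModel, np.ndarray]:
    """Scale relative loadings (noise-sd units) so each ROI's marginal sd
    equals ``total_sd``; returns the loading model and the matching noise sd.

    Working on the relative scale means planted correlations are set by
    loading ratios alone, and the marginal spread stays realistic for every
    ROI regardless of how many factors it rides."""
    lam_rel = np.atleast_2d(np.asarray(lam_rel, float))
    s = np.sqrt(1.0 + (lam_rel**2).sum(axis=1))
    scale = np.asarray(total_sd, float) / s
    return FactorModel(lam_rel * scale[:, None], np.ones(lam_rel.shape[1])), scale


def _block_rel(p: int, blocks: list[list[int]], pattern, global_load: float) -> np.ndarray:
    """Relative (noise-sd-unit) loadings: one factor per block with
    within-block loadings cycling through ``pattern``, plus one global."""
    pattern = np.atleast_1d(np.asarray(pattern, float))
    k = len(blocks)
    lam = np.zeros((p, k + 1))
    for j, idx in enumerate(blocks):
        for m, i in enumerate(idx):
            lam[i, j] = pattern[m % len(pattern)]
    lam[:, k] = global_load
    return lam


def _block_loadings(
    p: int, blocks: list[list[int]], pattern, global_load: float, total_sd: np.ndarray,
) -> tuple[FactorModel, np.ndarray]:
    """Variance-normalized block-plus-global factor model."""
    return _normalized_model(_block_rel(p, blocks, pattern, global_load), total_sd)


def _grid_loadings(
    rows: int, cols: int, load: float, global_load: float, total_sd: np.ndarray,
) -> tuple[FactorModel, np.ndarray]:
    """One factor per adjacent pair of a rows x cols lattice, plus a weak
    global factor; variance-normalized.  The implied correlation pattern is
    sparse and sequential — neighbours covary, nothing else does — so the
    thresholded network is lattice-like: few triangles, no integrative
    shortcuts."""
    p = rows * cols
    cols_list = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                vec = np.zeros(p)
                vec[i] = vec[i + 1] = load
                cols_list.append(vec)
            if r + 1 < rows:
                vec = np.zeros(p)
                vec[i] = vec[i + cols] = load
                cols_list.append(vec)
    cols_list.append(np.full(p, global_load))
    return _normalized_model(np.column_stack(cols_list), total_sd)


#: within-block loading pattern for the control-like module structure;
#: the graded weights let between-module edges enter the ranking early
#: enough that the thresholded network connects near the bottom of the
#: analyzed density range
_HC_PATTERN = (1.4, 1.1, 0.75, 0.45)


def paperlike_spec(seed: int = 0) -> CohortSpec:
    """Full-size three-group cohort over the 100-ROI catalog.

    The control group carries a seven-module block structure (bilateral
    basal ganglia plus amygdala/hippocampus/thalamus per hemisphere) with
    graded within-module loadings and a weak global factor.  Patient
    groups carry progressively weaker, less differentiated module
    structure with a stronger undifferentiated global component — at
    matched density their covariance networks are less clustered and less
    small-world, the currently-depressed group most so.
    """
    names = default_catalog().names
    p = len(names)
    base = _base_vector(names)
    total_sd = 0.12 * base
    blocks = _seven_module_blocks(names)
    pat = np.asarray(_HC_PATTERN)
    fm_hc, noise = _block_loadings(p, blocks, pat, 0.65, total_sd)
    # patient groups share the control group's noise scale so marker
    # shifts are comparable; their weaker loadings imply slightly smaller
    # marginal spread, which is immaterial for correlation structure
    rel_rd = _block_rel(p, blocks, 0.68 * pat, 0.8)
    rel_cm = _block_rel(p, blocks, 0.5 * pat, 0.9)
    fm_rd = FactorModel(rel_rd * noise[:, None], np.ones(rel_rd.shape[1]))
    fm_cm = FactorModel(rel_cm * noise[:, None], np.ones(rel_cm.shape[1]))
    return CohortSpec(
        roi_names=names,
        n_per_group={"cMDD": 131, "RD": 67, "HC": 235},
        age_distribution=_AGES,
        icv_distribution=_ICV,
        base_means=base,
        beta_age=-0.002 * base,
        beta_icv=0.6 * base / _ICV[0],
        noise_sd=noise,
        factor_model={"HC": fm_hc, "RD": fm_rd, "cMDD": fm_cm},
        marker_effects=list(_PAPERLIKE_MARKERS),
        gender_male_fraction=dict(_MALE_FRACTION),
        clinical=_CLINICAL,
        seed=seed,
    )


def _reduced_names(p: int = 20) -> list[str]:
    """A 20-ROI reduced catalog: the left-hemisphere basal ganglia,
    amygdala nuclei and the first seven hippocampal subfields."""
    return default_catalog().names[:p]


def tiny_spec(n: int = 30, seed: int = 0) -> CohortSpec:
    """Small, fast three-group spec over a 20-ROI reduced catalog."""
    names = _reduced_names(20)
    p = len(names)
    base = _base_vector(names)
    total_sd = 0.12 * base
    blocks = [list(range(0, 5)), list(range(5, 10)), list(range(10, 15)), list(range(15, 20))]
    pat = np.asarray(_HC_PATTERN)
    fm_hc, noise = _block_loadings(p, blocks, pat, 0.65, total_sd)
    rel_rd = _block_rel(p, blocks, 0.68 * pat, 0.8)
    rel_cm = _block_rel(p, blocks, 0.5 * pat, 0.9)
    fm = {
        "HC": fm_hc,
        "RD": FactorModel(rel_rd * noise[:, None], np.ones(rel_rd.shape[1])),
        "cMDD": FactorModel(rel_cm * noise[:, None], np.ones(rel_cm.shape[1])),
    }
    markers = [("L_Pallidum", "cMDD", -0.5 * noise[3]), ("L_Pallidum", "RD", -0.65 * noise[3])]
    return CohortSpec(
        roi_names=names,
        n_per_group={"cMDD": n, "RD": n, "HC": n},
        age_distribution=_AGES,
        icv_distribution=_ICV,
        base_means=base,
        beta_age=-0.002 * base,
        beta_icv=0.6 * base / _ICV[0],
        noise_sd=noise,
        factor_model=fm,
        marker_effects=markers,
        gender_male_fraction=dict(_MALE_FRACTION),
        clinical=_CLINICAL,
        seed=seed,
    )


def null_pair_spec(
    n: int = 40, groups: tuple[str, str] = ("cMDD", "HC"), seed: int = 0
) -> CohortSpec:
    """Two groups drawn from one identical law (weak global factor only)."""
    names = _reduced_names(20)
    p = len(names)
    base = _base_vector(names)
    fm_null, noise = _normalized_model(np.full((p, 1), 0.4), 0.12 * base)
    age = {g: (21.5, 3.5) for g in groups}
    return CohortSpec(
        roi_names=names,
        n_per_group={g: n for g in groups},
        age_distribution=age,
        icv_distribution=_ICV,
        base_means=base,
        beta_age=-0.002 * base,
        beta_icv=0.6 * base / _ICV[0],
        noise_sd=noise,
        factor_model={g: fm_null for g in groups},
        marker_effects=[],
        gender_male_fraction={g: 0.5 for g in groups},
        clinical={},
        seed=seed,
    )


def contrast_pair_spec(
    n: int = 100, groups: tuple[str, str] = ("cMDD", "HC"), seed: int = 0
) -> CohortSpec:
    """Two-group pair with a planted topological contrast (20 ROIs).

    Group 2 (control-like) carries four strong five-ROI modules plus a
    global factor: its thresholded network is modular and triangle-dense.
    Group 1 (patient-like) carries a sparse sequential lattice covariance
    (factors on adjacent pairs of a 4 x 5 grid): its network has few
    triangles and no integrative module structure, so it is markedly less
    clustered and less small-world, with a clearly separated
    characteristic-path-length curve.  At this node count the two path
    curves separate with the lattice group the shorter one — a matched-
    density consequence of its lower edge concentration — so the planted
    deficit reproduces the clustering/small-world direction of interest
    while the path-length contrast is detected two-tailed.
    """
    g1, g2 = groups
    names = _reduced_names(20)
    p = len(names)
    base = _base_vector(names)
    total_sd = 0.12 * base
    blocks = [list(range(0, 5)), list(range(5, 10)), list(range(10, 15)), list(range(15, 20))]
    fm_hc, noise = _block_loadings(p, blocks, 1.0, 0.6, total_sd)
    fm_grid, _ = _grid_loadings(4, 5, 1.6, 0.2, total_sd)
    age = {g: (21.5, 3.5) for g in groups}
    return CohortSpec(
        roi_names=names,
        n_per_group={g: n for g in groups},
        age_distribution=age,
        icv_distribution=_ICV,
        base_means=base,
        beta_age=-0.002 * base,
        beta_icv=0.6 * base / _ICV[0],
        noise_sd=noise,
        factor_model={g2: fm_hc, g1: fm_grid},
        marker_effects=[],
        gender_male_fraction={g: 0.5 for g in groups},
        clinical={},
        seed=seed,
    )
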