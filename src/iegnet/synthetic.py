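"""Synthetic study generator.

The raw densitometry data of the motivating study design are not
deposited, so this module generates datasets with the statistical
structure the downstream analysis assumes: four treatment arms
(VEH/VEH, VEH/ASE, KET/VEH, KET/ASE), five animals per arm, 33 ROIs,
three adjacent-section replicates per animal, and group-specific mean
shifts plus group-specific inter-ROI correlation structure.

Animal-level ROI vectors are drawn from a multivariate normal with a
target correlation matrix (imposed through its symmetric eigenvalue
factorization), scaled by per-ROI marginal SDs and shifted by per-ROI
means — the same normality the analysis itself assumes.  Section
replicates add independent Gaussian noise on top of the animal value;
the gcc reference channel is drawn independently per animal.  Raw
section values are emitted as (normalized animal value x same-animal
gcc), so running the generated long-format file back through the
data-model stage (section averaging + ratio normalization) recovers
the generated animal-level table exactly when the section noise is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .data import ExpressionTable, SectionMeasurement, StudyDataset
from .registry import ROIRegistry, default_registry

__all__ = [
    "SyntheticGroupConfig",
    "SyntheticStudyConfig",
    "make_study_template",
    "generate",
    "nearest_correlation",
    "block_correlation",
    "save_config",
    "load_config",
    "STUDY_GROUPS",
    "ROI_BLOCKS",
]

#: The four treatment arms of the study design (pre-treatment/treatment).
STUDY_GROUPS = ("VEH/VEH", "VEH/ASE", "KET/VEH", "KET/ASE")

PSD_TOL = -1e-8

#: Anatomical families used for block-structured correlation presets.
ROI_BLOCKS: dict[str, tuple[str, ...]] = {
    "septal": ("LSV", "LSD", "LSI", "MS", "VDB", "Shi", "IG"),
    "ventral_striatal": ("Tu", "Icj", "VP", "AcSh", "AcCo", "LSS"),
    "dorsal_striatal": ("CPDL", "CPVL", "CPVM", "CPDM"),
    "insular": ("AIV", "GI", "DI", "AID", "Den", "Pir", "Cl"),
    "cortical": ("S1dz", "S1ULp", "Cg2", "Cg1", "M2", "M1", "S1Fl", "S1j", "S1jO"),
}


def _validate_correlation(C: np.ndarray, tol: float = PSD_TOL) -> None:
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have a unit diagonal")
    w = np.linalg.eigvalsh(C)
    if w.min() < tol:
        raise ValueError(
            f"correlation matrix is not positive semi-definite "
            f"(min eigenvalue {w.min():.3g})"
        )


def nearest_correlation(C: np.ndarray, n_iter: int = 100) -> np.ndarray:
    """Project a symmetric matrix to a nearby valid correlation matrix.

    Alternates eigenvalue clipping (at a small positive floor) with
    unit-diagonal rescaling — a light-weight variant of Higham's
    alternating projections, sufficient for preset construction.
    """
    X = np.asarray(C, dtype=float).copy()
    X = (X + X.T) / 2
    for _ in range(n_iter):
        w, U = np.linalg.eigh(X)
        if w.min() >= 1e-10:
            break
        w = np.clip(w, 1e-10, None)
        X = (U * w) @ U.T
        d = np.sqrt(np.diag(X))
        X = X / np.outer(d, d)
        X = (X + X.T) / 2
    np.fill_diagonal(X, 1.0)
    return X


def block_correlation(
    registry: ROIRegistry,
    within: float = 0.6,
    between: float = 0.2,
    blocks: dict[str, tuple[str, ...]] | None = None,
) -> np.ndarray:
    """Block-structured correlation over the registry's ROIs.

    The result is PSD by construction when ``within >= between >= 0``:
    it decomposes into a global factor, per-block factors, and a
    positive diagonal remainder.
    """
    blocks = blocks if blocks is not None else ROI_BLOCKS
    rois = registry.abbreviations
    m = len(rois)
    block_of = {}
    for name, members in blocks.items():
        for roi in members:
            block_of[roi] = name
    C = np.full((m, m), between, dtype=float)
    for i, a in enumerate(rois):
        for j, b in enumerate(rois):
            if block_of.get(a) is not None and block_of.get(a) == block_of.get(b):
                C[i, j] = within
    np.fill_diagonal(C, 1.0)
    return C


@dataclass
class SyntheticGroupConfig:
    """Generative parameters of one treatment group."""

    group: str
    roi_means: np.ndarray
    correlation: np.ndarray
    animal_sd: np.ndarray
    n_animals: int = 5
    n_sections: int = 3
    section_sd: float = 0.0
    reference_mean: float = 1.0
    reference_sd: float = 0.05
    clip_negative: bool = False

    def __post_init__(self) -> None:
        self.roi_means = np.asarray(self.roi_means, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        self.animal_sd = np.broadcast_to(
            np.asarray(self.animal_sd, dtype=float), self.roi_means.shape
        ).copy()

    def validate(self, n_rois: int) -> None:
        if self.n_animals < 3:
            raise ValueError(f"group {self.group!r}: n_animals must be >= 3")
        if self.n_sections < 1:
            raise ValueError(f"group {self.group!r}: n_sections must be >= 1")
        if self.roi_means.shape != (n_rois,):
            raise ValueError(f"group {self.group!r}: roi_means has wrong length")
        if self.correlation.shape != (n_rois, n_rois):
            raise ValueError(f"group {self.group!r}: correlation has wrong shape")
        if (self.animal_sd < 0).any() or self.section_sd < 0 or self.reference_sd < 0:
            raise ValueError(f"group {self.group!r}: standard deviations must be >= 0")
        _validate_correlation(self.correlation)


@dataclass
class SyntheticStudyConfig:
    """Registry, per-group configs, and the mandatory master seed."""

    registry: ROIRegistry
    groups: list[SyntheticGroupConfig]
    seed: int = 0
    preset: str | None = None

    def validate(self) -> None:
        labels = [g.group for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels in synthetic config")
        for g in self.groups:
            g.validate(self.registry.n_rois)


def make_study_template(
    preset: str = "null",
    *,
    registry: ROIRegistry | None = None,
    n_animals: int = 5,
    n_sections: int = 3,
    section_sd: float | None = None,
    pair: tuple[str, str] = ("CPDM", "CPDL"),
    delta_r: float = 0.9,
    seed: int = 0,
) -> SyntheticStudyConfig:
    """Build a preset study configuration.

    Presets
    -------
    ``null``
        Four arms with byte-identical generative parameters (no group
        differences): block-structured baseline correlation, common
        means — the type-I-error calibration condition.
    ``paper_like``
        Four arms; the KET/VEH-like arm carries a negative IG
        (indusium griseum) correlation row and lowered dorsal-striatal
        and medial-septum means, while the KET/ASE-like arm restores
        the baseline (positive) structure with raised means.
    ``edge_difference``
        Two arms ("A", "B") whose correlation matrices differ in
        exactly one ROI pair (``pair``), by ``delta_r``.
    """
    registry = registry or default_registry()
    m = registry.n_rois
    rois = registry.abbreviations
    base_means = np.full(m, 0.5)
    base_sd = np.full(m, 0.15)

    def group_cfg(label, means, corr, sect_sd):
        return SyntheticGroupConfig(
            group=label,
            roi_means=means,
            correlation=corr,
            animal_sd=base_sd,
            n_animals=n_animals,
            n_sections=n_sections,
            section_sd=sect_sd,
        )

    if preset == "null":
        corr = block_correlation(registry)
        sect = 0.0 if section_sd is None else section_sd
        groups = [group_cfg(g, base_means.copy(), corr.copy(), sect) for g in STUDY_GROUPS]
    elif preset == "paper_like":
        sect = 0.02 if section_sd is None else section_sd
        base = block_correlation(registry)
        ig = registry.index("IG")
        ket_corr = base.copy()
        ket_corr[ig, :] = -0.6
        ket_corr[:, ig] = -0.6
        ket_corr[ig, ig] = 1.0
        ket_corr = nearest_correlation(ket_corr)
        low = np.array(
            [a in ROI_BLOCKS["dorsal_striatal"] or a == "MS" for a in rois]
        )
        ket_means = np.where(low, 0.25, 0.45)
        ketase_means = np.where(low, 0.70, 0.55)
        groups = [
            group_cfg("VEH/VEH", base_means.copy(), base.copy(), sect),
            group_cfg("VEH/ASE", base_means.copy(), base.copy(), sect),
            group_cfg("KET/VEH", ket_means, ket_corr, sect),
            group_cfg("KET/ASE", ketase_means, base.copy(), sect),
        ]
    elif preset == "edge_difference":
        sect = 0.0 if section_sd is None else section_sd
        i, j = registry.index(pair[0]), registry.index(pair[1])
        corr_a = np.eye(m)
        corr_a[i, j] = corr_a[j, i] = delta_r
        corr_b = np.eye(m)
        groups = [
            group_cfg("A", base_means.copy(), corr_a, sect),
            group_cfg("B", base_means.copy(), corr_b, sect),
        ]
    else:
        raise ValueError(f"unknown preset {preset!r}")

    config = SyntheticStudyConfig(
        registry=registry, groups=groups, seed=seed, preset=preset
    )
    config.validate()
    return config


def _mvn_factor(C: np.ndarray) -> np.ndarray:
    """Symmetric square-root factor of a PSD correlation matrix."""
    w, U = np.linalg.eigh(C)
    return U * np.sqrt(np.clip(w, 0.0, None))


def generate(
    config: SyntheticStudyConfig,
) -> tuple[list[SectionMeasurement], StudyDataset]:
    """Draw one synthetic study: raw long-format rows plus the ground truth.

    The returned :class:`StudyDataset` holds the animal-level normalized
    values (the generative truth); the measurement list is the raw
    long-format view, including the gcc channel, suitable for
    :func:`iegnet.data.write_long_table` and a full pipeline re-run.
    The same seed always yields identical output.
    """
    config.validate()
    rois = config.registry.abbreviations
    ref = config.registry.reference_roi
    children = np.random.SeedSequence(config.seed).spawn(len(config.groups))

    measurements: list[SectionMeasurement] = []
    tables: dict[str, ExpressionTable] = {}
    for gcfg, child in zip(config.groups, children):
        rng = np.random.default_rng(child)
        m = len(rois)
        F = _mvn_factor(gcfg.correlation)
        Z = rng.standard_normal((gcfg.n_animals, m))
        V = gcfg.roi_means + (Z @ F.T) * gcfg.animal_sd
        if gcfg.clip_negative:
            V = np.clip(V, 0.0, None)
        gcc = rng.normal(gcfg.reference_mean, gcfg.reference_sd, gcfg.n_animals)
        gcc = np.clip(gcc, 1e-6, None)  # reference must stay usable as a divisor

        animals = [f"{gcfg.group}_a{i + 1}" for i in range(gcfg.n_animals)]
        raw = V * gcc[:, None]
        for s in range(gcfg.n_sections):
            noise = rng.normal(0.0, gcfg.section_sd, (gcfg.n_animals, m))
            ref_noise = rng.normal(0.0, gcfg.section_sd, gcfg.n_animals)
            for i, animal in enumerate(animals):
                for j, roi in enumerate(rois):
                    measurements.append(
                        SectionMeasurement(
                            animal_id=animal,
                            group=gcfg.group,
                            roi=roi,
                            section=s + 1,
                            value=max(float(raw[i, j] + noise[i, j]), 0.0),
                        )
                    )
                measurements.append(
                    SectionMeasurement(
                        animal_id=animal,
                        group=gcfg.group,
                        roi=ref,
                        section=s + 1,
                        value=max(float(gcc[i] + ref_noise[i]), 0.0),
                    )
                )
        tables[gcfg.group] = ExpressionTable(
            group=gcfg.group, animals=animals, rois=list(rois), values=V
        )

    dataset = StudyDataset(
        registry=config.registry,
        tables=tables,
        provenance={
            "source": "synthetic",
            "preset": config.preset,
            "seed": config.seed,
            "normalization_mode": "ratio",
        },
    )
    return measurements, dataset


def save_config(config: SyntheticStudyConfig, path: str | Path) -> Path:
    """Serialize a synthetic config to YAML."""
    payload = {
        "seed": int(config.seed),
        "preset": config.preset,
        "registry": {
            "entries": [list(e) for e in config.registry.entries],
            "reference_roi": config.registry.reference_roi,
        },
        "groups": [
            {
                "group": g.group,
                "roi_means": g.roi_means.tolist(),
                "correlation": g.correlation.tolist(),
                "animal_sd": g.animal_sd.tolist(),
                "n_animals": int(g.n_animals),
                "n_sections": int(g.n_sections),
                "section_sd": float(g.section_sd),
                "reference_mean": float(g.reference_mean),
                "reference_sd": float(g.reference_sd),
                "clip_negative": bool(g.clip_negative),
            }
            for g in config.groups
        ],
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def load_config(path: str | Path) -> SyntheticStudyConfig:
    payload = yaml.safe_load(Path(path).read_text())
    registry = ROIRegistry(
        entries=tuple(tuple(e) for e in payload["registry"]["entries"]),
        reference_roi=payload["registry"]["reference_roi"],
    )
    groups = [SyntheticGroupConfig(**g) for g in payload["groups"]]
    config = SyntheticStudyConfig(
        registry=registry,
        groups=groups,
        seed=int(payload["seed"]),
        preset=payload.get("preset"),
    )
    config.validate()
    return config
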