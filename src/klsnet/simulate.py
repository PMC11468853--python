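"""Synthetic two-group cohorts of parcellated GM voxel-value distributions.

Real per-subject GM volume maps are not redistributable, so every pipeline
stage is exercised on simulated cohorts with known ground truth.  Each
region's voxel values are drawn from a truncated-at-zero Gaussian whose mean
varies between subjects; patients additionally receive deterministic mean
offsets in selected regions so that

* chosen region *pairs* lose similarity (their KLS edge weight drops by a
  controlled effect size) — a plantable NBS-style subnetwork effect, and
* a chosen region drifts away from *all* others — a plantable nodal
  degree/efficiency reduction.

Effects are planted on the distributions, never on the KLS values directly,
so the whole KDE -> KL -> KLS chain is exercised rather than bypassed.

Effect-size calibration
-----------------------
``similarity_shift`` is expressed as the target between-group effect size
(Cohen's d) of the affected KLS edge, in pooled-SD units of that edge across
subjects.  For two regions whose voxel distributions are Gaussian with
common scale ``sigma`` and whose subject-level means differ by
``delta ~ N(u * sqrt(2) * tau * sigma, 2 tau^2 sigma^2)``, the symmetric KL
divergence is approximately ``(delta / sigma_eff)^2`` (``sigma_eff``
includes the KDE bandwidth inflation), which makes KLS = exp(-D) a
lognormal-of-noncentral-chi-square variable with closed-form mean and
variance.  The generator inverts that relation numerically to find the mean
separation ``u`` that produces the requested edge-level d, then assigns the
planted regions equally spaced patient mean offsets with that spacing, so
every planted pair receives *at least* the requested effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .atlas import AtlasSpec, SubjectParcellation

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "generate_niftis",
    "small_test_spec",
    "planted_test_spec",
]


@dataclass(frozen=True)
class CohortSpec:
    """Generator settings for a two-group parcellated cohort.

    Defaults describe a typical case-control cohort: 55 patients vs 57
    controls, 116 atlas regions.  ``small_test_spec`` /
    ``planted_test_spec`` provide a 12-region desk-scale configuration.
    """

    n_patients: int = 55
    n_controls: int = 57
    n_regions: int = 116
    voxels_per_region: tuple[int, int] = (250, 350)
    base_loc: float = 0.5
    base_scale: float = 0.1
    subject_sd_frac: float = 0.3          # tau: between-subject SD of a region
                                          # mean, in units of base_scale
    planted_edges: tuple[tuple[int, int, float], ...] = ()
    planted_node: int | None = None
    planted_node_shift: float = 3.0
    sex_male_p: float = 0.15
    age_mean: float = 46.0
    age_sd: float = 12.3
    edu_mean: float = 11.0
    edu_sd: float = 4.8
    patient_age_shift: float = 0.0        # group difference in mean age (confound)
    age_coef: float = 0.0                 # per-SD-of-age shift of all region
                                          # means, in units of tau * base_scale
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("both groups need at least one subject")
        ids = set(range(1, self.n_regions + 1))
        for i, j, s in self.planted_edges:
            if i == j or i not in ids or j not in ids:
                raise ValueError(f"planted edge ({i}, {j}) references invalid regions")
            if s <= 0:
                raise ValueError("similarity_shift must be positive")
        if self.planted_node is not None and self.planted_node not in ids:
            raise ValueError("planted_node references an invalid region")

    @property
    def atlas(self) -> AtlasSpec:
        return AtlasSpec(tuple(range(1, self.n_regions + 1)))


def _edge_effect_to_mean_separation(
    shift: float, tau: float, n_voxels: int
) -> float:
    """Invert the KLS effect-size model: target edge d -> mean separation u.

    ``u`` is in units of sqrt(2) * tau * sigma (the between-subject SD of the
    pairwise region-mean difference).  Uses the Gaussian approximation
    described in the module docstring; an unreachable target raises.
    """
    bw_factor = n_voxels ** (-1 / 5)                   # Scott, 1-D
    c = 2 * tau**2 / (1 + bw_factor**2)

    e0 = (1 + 2 * c) ** -0.5
    m2_0 = (1 + 4 * c) ** -0.5
    var0 = m2_0 - e0**2

    def d_of_u(u: float) -> float:
        lam = u**2
        ep = e0 * np.exp(-c * lam / (1 + 2 * c))
        m2 = m2_0 * np.exp(-2 * c * lam / (1 + 4 * c))
        varp = max(m2 - ep**2, 1e-12)
        return (e0 - ep) / np.sqrt((var0 + varp) / 2)

    d_max = e0 / np.sqrt(var0 / 2)
    if shift >= d_max:
        raise ValueError(
            f"similarity_shift {shift} exceeds the attainable edge effect "
            f"({d_max:.2f}) for these noise settings (degenerate separation)"
        )
    return float(brentq(lambda u: d_of_u(u) - shift, 1e-6, 1e3))


def _patient_offsets(spec: CohortSpec) -> np.ndarray:
    """Deterministic per-region patient mean offsets implementing the plants."""
    tau_sigma = spec.subject_sd_frac * spec.base_scale
    n_vox = int(np.mean(spec.voxels_per_region))
    offsets = np.zeros(spec.n_regions)
    if spec.planted_edges:
        nodes = sorted({r for i, j, _ in spec.planted_edges for r in (i, j)})
        max_shift = max(s for _, _, s in spec.planted_edges)
        u = _edge_effect_to_mean_separation(max_shift, spec.subject_sd_frac, n_vox)
        spacing = u * np.sqrt(2) * tau_sigma
        for rank, node in enumerate(nodes):
            offsets[node - 1] += rank * spacing
    if spec.planted_node is not None:
        u = _edge_effect_to_mean_separation(
            spec.planted_node_shift, spec.subject_sd_frac, n_vox
        )
        offsets[spec.planted_node - 1] += u * np.sqrt(2) * tau_sigma
    return offsets


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[SubjectParcellation], pd.DataFrame, dict]:
    """Simulate a cohort: parcellations, phenotype table and ground truth.

    Controls draw every region from its base distribution; patients get the
    planted mean offsets on top.  Covariates (sex, age, education) are drawn
    from matched distributions unless a confound is configured.  Bitwise
    reproducible for a fixed ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_total = spec.n_patients + spec.n_controls
    lo, hi = spec.voxels_per_region
    counts = rng.integers(lo, hi + 1, size=spec.n_regions)
    tau_sigma = spec.subject_sd_frac * spec.base_scale
    offsets = _patient_offsets(spec)

    group = np.array([1] * spec.n_patients + [0] * spec.n_controls)
    sex = (rng.random(n_total) < spec.sex_male_p).astype(int)
    age = rng.normal(spec.age_mean, spec.age_sd, n_total)
    age[group == 1] += spec.patient_age_shift
    edu = np.abs(rng.normal(spec.edu_mean, spec.edu_sd, n_total))

    parcs: list[SubjectParcellation] = []
    for s_idx in range(n_total):
        sid = f"{'vm' if group[s_idx] else 'hc'}{s_idx:03d}"
        values: dict[int, np.ndarray] = {}
        age_term = spec.age_coef * tau_sigma * (age[s_idx] - spec.age_mean) / spec.age_sd
        for r in range(spec.n_regions):
            mean = spec.base_loc + tau_sigma * rng.standard_normal() + age_term
            if group[s_idx]:
                mean = mean + offsets[r]
            a = (0.0 - mean) / spec.base_scale
            values[r + 1] = truncnorm.rvs(
                a, np.inf, loc=mean, scale=spec.base_scale,
                size=int(counts[r]), random_state=rng,
            )
        parcs.append(SubjectParcellation(sid, values))

    phenotype = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in parcs],
            "group": group,
            "sex": sex,
            "age": age,
            "education": edu,
        }
    )
    truth = {
        "planted_edges": [list(e) for e in spec.planted_edges],
        "planted_node": spec.planted_node,
        "planted_node_shift": spec.planted_node_shift,
        "patient_offsets": offsets.tolist(),
        "voxel_counts": counts.tolist(),
        "rng_seed": spec.rng_seed,
        "spec": asdict(spec),
    }
    return parcs, phenotype, truth


# ---------------------------------------------------------------------------
# NIfTI export (desk-scale; regions laid out as z-slices of a block volume)
# ---------------------------------------------------------------------------

def generate_niftis(spec: CohortSpec, out_dir: str | Path) -> dict:
    """Write per-subject GM NIfTI volumes plus one atlas NIfTI.

    Region r occupies the first ``voxel_count[r]`` voxels (C scan order) of
    z-slice r - 1; extraction through :func:`klsnet.atlas.extract_roi_values`
    reproduces the in-memory parcellations exactly.  Also writes the
    phenotype CSV and a ground-truth JSON.  Intended for small test specs
    (say <= 20 regions).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    parcs, phenotype, truth = generate_cohort(spec)
    counts = truth["voxel_counts"]
    side = int(np.ceil(np.sqrt(max(counts))))
    shape = (side, side, spec.n_regions)

    atlas_vol = np.zeros(shape, dtype=np.int16)
    for r, count in enumerate(counts):
        plane = np.zeros(side * side, dtype=np.int16)
        plane[:count] = r + 1
        atlas_vol[:, :, r] = plane.reshape(side, side)
    affine = np.eye(4)
    atlas_path = out_dir / "atlas.nii.gz"
    nib.save(nib.Nifti1Image(atlas_vol, affine), str(atlas_path))

    subject_paths = {}
    for p in parcs:
        vol = np.zeros(shape, dtype=np.float64)
        for r in range(spec.n_regions):
            plane = np.zeros(side * side)
            plane[: counts[r]] = p.values[r + 1]
            vol[:, :, r] = plane.reshape(side, side)
        path = out_dir / f"{p.subject_id}_gm.nii.gz"
        nib.save(nib.Nifti1Image(vol, affine), str(path))
        subject_paths[p.subject_id] = str(path)

    phenotype.to_csv(out_dir / "phenotype.csv", index=False)
    spec.atlas.to_table(out_dir / "atlas_regions.tsv")
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return {
        "atlas": str(atlas_path),
        "atlas_table": str(out_dir / "atlas_regions.tsv"),
        "subjects": subject_paths,
        "phenotype": str(out_dir / "phenotype.csv"),
        "ground_truth": str(out_dir / "ground_truth.json"),
    }


# ---------------------------------------------------------------------------
# canonical desk-scale specs
# ---------------------------------------------------------------------------

def small_test_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Null 12-region cohort (20 + 20 subjects, 300 voxels/region)."""
    kwargs = dict(
        n_patients=20, n_controls=20, n_regions=12,
        voxels_per_region=(300, 300), rng_seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


def planted_test_spec(
    seed: int = 0, edge_shift: float = 1.5, node_shift: float = 3.0, **overrides
) -> CohortSpec:
    """Desk-scale cohort with a 10-edge planted subnetwork and a planted node.

    The subnetwork is the complete graph on regions 1-5 (10 edges), each
    edge weakened in patients by at least ``edge_shift`` pooled SDs; region 8
    additionally drifts from all others by ``node_shift``.
    """
    nodes = (1, 2, 3, 4, 5)
    edges = tuple(
        (nodes[a], nodes[b], edge_shift)
        for a in range(len(nodes))
        for b in range(a + 1, len(nodes))
    )
    kwargs = dict(planted_edges=edges, planted_node=8, planted_node_shift=node_shift)
    kwargs.update(overrides)
    return small_test_spec(seed, **kwargs)
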