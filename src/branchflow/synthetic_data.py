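"""Synthetic labeled arbors with controlled branching statistics.

The generator produces complete binary trees whose junction-level radius
and length scale factors follow prescribed profiles, discretized as valid
SWC sample chains. Complete trees (no random topology) keep the relative
leaf number of every junction analytic: a junction whose parent branch
sits at generation g of a depth-d tree has parent leaf number 2^(d-g) and
relative leaf number exactly g. Randomness enters only through truncated
Gaussian noise on the ratio draws and optional geometric jitter, so the
expected extracted features are closed-form.

A quantization operator emulates the imaging resolution floor: once true
radii fall below the pixel size, all recorded radii collapse to the pixel
size, producing spurious daughter/parent ratios of exactly 1 — the
artifact the downstream beta >= 0.999 filter removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .swc_io import Reconstruction, SwcSample, SOMA_TYPE

__all__ = [
    "ArborSpec",
    "CohortSpec",
    "generate_arbor",
    "quantize_radii",
    "generate_cohort",
    "constant_profile",
    "level_localized_specs",
]

# clip band keeping every ratio strictly inside (0, 1) and clear of the
# resolution-filter threshold
_RATIO_LO = 0.01
_RATIO_HI = 0.999 * 0.999

Profile = Callable[[int], float]


def constant_profile(value: float) -> Profile:
    """Profile returning the same target at every junction level."""
    return lambda level: value


def _as_profile(p: "Profile | float") -> Profile:
    return p if callable(p) else constant_profile(float(p))


@dataclass
class ArborSpec:
    """Parameters of one synthetic arbor.

    depth
        Number of branching generations; the tree has 2**depth tips and
        2**(depth+1) - 1 branches.
    root_radius, root_length
        Radius and length of the root branch, micrometres.
    beta_mean_profile, beta_diff_profile
        Target mean and (signed) half-difference radius scale factors per
        junction level (level == the junction's relative leaf number on a
        complete tree); scalars are promoted to constant profiles.
    gamma_mean, gamma_diff
        Length scale factors (gamma_diff >= 0; daughter 1 is the longer).
    noise_sd
        SD of truncated Gaussian noise added independently to the mean and
        half-difference draws at each junction.
    samples_per_branch
        Number of SWC samples per branch (>= 2), evenly spaced; radii are
        constant along a branch so the per-branch mean radius is exact.
    jitter_sd
        SD (micrometres) of perpendicular positional jitter on interior
        samples; 0 keeps branches perfectly straight.
    pixel_size
        If > 0, radii are quantized to this grid after generation.
    shuffle_levels
        If True, each junction's profiles are evaluated at a level drawn
        from the tree's junction-count distribution (2**g junctions at
        level g) instead of the true level. The pooled per-junction ratio
        marginals are then *identical in distribution* to the unshuffled
        arbor's, but decoupled from junction position — the null partner
        for level-localized comparisons.
    """

    depth: int = 5
    root_radius: float = 1.0
    root_length: float = 100.0
    beta_mean_profile: "Profile | float" = 0.7
    beta_diff_profile: "Profile | float" = 0.1
    gamma_mean: float = 0.8
    gamma_diff: float = 0.1
    noise_sd: float = 0.0
    samples_per_branch: int = 5
    jitter_sd: float = 0.0
    pixel_size: float = 0.0
    shuffle_levels: bool = False
    type_code: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.samples_per_branch < 2:
            raise ValueError("samples_per_branch must be >= 2")
        if self.root_radius <= 0 or self.root_length <= 0:
            raise ValueError("root_radius and root_length must be positive")
        if self.gamma_diff < 0 or self.gamma_mean - self.gamma_diff <= 0:
            raise ValueError("need gamma_diff >= 0 and gamma_mean - gamma_diff > 0")
        bm = _as_profile(self.beta_mean_profile)
        bd = _as_profile(self.beta_diff_profile)
        for g in range(self.depth):
            lo = bm(g) - abs(bd(g))
            hi = bm(g) + abs(bd(g))
            if not (_RATIO_LO < lo and hi < _RATIO_HI):
                raise ValueError(
                    f"level {g}: profile ratios ({lo:.4f}, {hi:.4f}) outside the "
                    f"admissible band ({_RATIO_LO}, {_RATIO_HI:.4f})"
                )


@dataclass
class CohortSpec:
    """A labeled cohort: one ArborSpec per class, n cells per class."""

    class_specs: Mapping[str, ArborSpec]
    n_cells_per_class: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not self.class_specs:
            raise ValueError("cohort needs at least one class")
        if self.n_cells_per_class < 2:
            raise ValueError("need >= 2 cells per class")
        for spec in self.class_specs.values():
            spec.validate()


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_arbor(spec: ArborSpec, cell_id: str = "synthetic", label: str | None = None) -> Reconstruction:
    """Generate one complete-binary-tree arbor as a Reconstruction.

    Deterministic for a given spec (including seed). The soma is a single
    type-1 sample at the origin; each branch is ``samples_per_branch``
    evenly spaced constant-radius samples, so branch extraction recovers
    the constructed tree exactly: 2**depth tips, 2**(depth+1) - 1 branches.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bm_prof = _as_profile(spec.beta_mean_profile)
    bd_prof = _as_profile(spec.beta_diff_profile)

    samples: list[SwcSample] = [
        SwcSample(1, SOMA_TYPE, 0.0, 0.0, 0.0, float(spec.root_radius), -1)
    ]
    next_id = 2
    n_clipped = 0

    # stack of branches to emit: (generation, radius, length, start_point,
    # direction, parent_sample_id)
    root_dir = _unit(rng.standard_normal(3))
    stack = [(0, float(spec.root_radius), float(spec.root_length),
              np.zeros(3), root_dir, 1)]
    # emit depth-first; rng draws are therefore consumed in a fixed order
    while stack:
        gen, radius, length, p0, u, parent_sid = stack.pop()
        m = spec.samples_per_branch
        first_sid = next_id
        for i in range(1, m + 1):
            pos = p0 + u * (length * i / m)
            if spec.jitter_sd > 0 and i < m:
                perp = rng.standard_normal(3)
                perp -= perp.dot(u) * u
                pos = pos + spec.jitter_sd * perp
            samples.append(
                SwcSample(next_id, spec.type_code, float(pos[0]), float(pos[1]),
                          float(pos[2]), float(radius),
                          parent_sid if i == 1 else next_id - 1)
            )
            next_id += 1
        last_sid = next_id - 1
        end = p0 + u * length
        if gen < spec.depth:
            lvl = gen
            if spec.shuffle_levels:
                w = 2.0 ** np.arange(spec.depth)
                lvl = int(rng.choice(spec.depth, p=w / w.sum()))
            bm = bm_prof(lvl)
            bd = bd_prof(lvl)
            if spec.noise_sd > 0:
                bm = bm + spec.noise_sd * rng.standard_normal()
                bd = bd + spec.noise_sd * rng.standard_normal()
            b1, b2 = bm + bd, bm - bd  # daughter 1 = longer daughter
            b1c = float(np.clip(b1, _RATIO_LO, _RATIO_HI))
            b2c = float(np.clip(b2, _RATIO_LO, _RATIO_HI))
            n_clipped += (b1c != b1) + (b2c != b2)
            g1 = spec.gamma_mean + spec.gamma_diff
            g2 = spec.gamma_mean - spec.gamma_diff
            for ratio_r, ratio_l in ((b1c, g1), (b2c, g2)):
                d = _unit(u + 0.9 * rng.standard_normal(3))
                stack.append(
                    (gen + 1, radius * ratio_r, length * ratio_l, end, d, last_sid)
                )
    rec = Reconstruction(samples=samples, cell_id=cell_id, label=label,
                         source=f"branchflow synthetic seed={spec.seed}")
    if spec.pixel_size > 0:
        rec = quantize_radii(rec, spec.pixel_size)
    return rec


def quantize_radii(rec: Reconstruction, pixel_size: float) -> Reconstruction:
    """Snap radii to the imaging pixel grid with a one-pixel floor.

    Each radius becomes ``max(pixel_size, pixel_size * round(r / pixel_size))``;
    ``pixel_size == 0`` is the identity. Deep branches thinner than one
    pixel collapse to equal radii, so their junctions show beta == 1 —
    exactly the spurious ratios the resolution filter removes.
    """
    if pixel_size < 0:
        raise ValueError("pixel_size must be >= 0")
    if pixel_size == 0:
        return rec
    new = [
        replace(s, radius=max(pixel_size, pixel_size * round(s.radius / pixel_size)))
        for s in rec.samples
    ]
    return Reconstruction(samples=new, cell_id=rec.cell_id, label=rec.label,
                          source=rec.source)


def _cell_seed(cohort_seed: int, class_idx: int, cell_idx: int) -> int:
    """Counter-based per-cell seed derivation, stable across generation order."""
    ss = np.random.SeedSequence(entropy=cohort_seed, spawn_key=(class_idx, cell_idx))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(cohort: CohortSpec) -> tuple[list[Reconstruction], pd.DataFrame]:
    """Generate a labeled cohort of arbors plus its manifest.

    Returns the reconstructions and a manifest DataFrame with columns
    (cell_id, label, seed). Per-cell seeds are derived from the cohort
    seed via counter-based SeedSequence spawning, so the cohort is
    reproducible regardless of generation order.
    """
    cohort.validate()
    recs: list[Reconstruction] = []
    rows = []
    for class_idx, (label, spec) in enumerate(cohort.class_specs.items()):
        for cell_idx in range(cohort.n_cells_per_class):
            seed = _cell_seed(cohort.seed, class_idx, cell_idx)
            cell_id = f"{label}_{cell_idx:03d}"
            rec = generate_arbor(replace(spec, seed=seed), cell_id=cell_id, label=label)
            recs.append(rec)
            rows.append({"cell_id": cell_id, "label": label, "seed": seed})
    return recs, pd.DataFrame(rows)


def level_localized_specs(
    depth: int = 6,
    base_beta_mean: float = 0.65,
    slope: float = 0.05,
    noise_sd: float = 0.03,
    beta_diff: float = 0.08,
    **common,
) -> tuple[ArborSpec, ArborSpec]:
    """Two arbor specs whose classes differ only in level-localized structure.

    Both classes draw their ratios from the same level-dependent profile —
    mean radius scale factor rising linearly with junction level, centered
    on the junction-count-weighted mean level — so the pooled per-junction
    marginals of the two classes are identical in distribution. In class A
    the profile is evaluated at the junction's true level; class B
    shuffles levels (draws them from the junction-count distribution), so
    its ratios are independent of position. Conditioned on the relative
    leaf number the class means differ while the 2-feature marginals do
    not: the astrocyte/microglia-like regime where adding the junction
    position feature is what makes the comparison classifiable.
    """
    g = np.arange(depth)
    w = 2.0**g
    w = w / w.sum()
    g_mean = float(w @ g)

    def profile(level: int, _a=base_beta_mean, _s=slope, _g0=g_mean) -> float:
        return _a + _s * (level - _g0)

    spec_a = ArborSpec(
        depth=depth,
        beta_mean_profile=profile,
        beta_diff_profile=beta_diff,
        noise_sd=noise_sd,
        **common,
    )
    spec_b = replace(spec_a, shuffle_levels=True)
    return spec_a, spec_b
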