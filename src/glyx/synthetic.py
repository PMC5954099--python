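"""Seeded generators for every input the pipeline consumes.

Three families of synthetic data stand in for the study's raw measurements:

* confocal z-stacks of a probe distributed along a 2-4 um endothelial-scale
  glycocalyx, acquired at 0.2 um z-spacing, with an axial Gaussian PSF,
  Poisson shot noise, Gaussian read noise and stepwise geometric
  photobleaching (only axial blur is modelled — the quadrant analysis is
  purely axial);
* electrophoretic mobility datasets produced by the soft-layer model of
  :mod:`glyx.electrokinetics` plus Gaussian measurement noise;
* flow-cytometry MFI tables with log-normal event intensities (CV on the
  log scale) reduced to a replicate MFI by the median over events.

All generators are byte-deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import electrokinetics as ek
from .errors import InvalidParameterError
from .zstack import RoiMask, ZStack

PROBE_DISTRIBUTIONS = ("uniform", "outer", "compressed")


# --------------------------------------------------------------------------
# stack specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StackSpec:
    """Geometry, optics and noise of one synthetic confocal acquisition.

    The probe occupies ``[membrane_z, membrane_z + glyx_height]`` (um) with an
    axial density chosen by ``probe_distribution``:

    * ``uniform`` — constant over the whole layer;
    * ``outer`` — constant over ``[membrane_z + outer_z_lo, membrane_z +
      glyx_height]``, zero below (total mass conserved);
    * ``compressed`` — the uniform layer squeezed toward the membrane by
      factor ``compression``; with ``conserve_mass`` the per-slice density
      scales by ``1/compression``.

    ``membrane_z`` should sit at a slice centre so the membrane focus peak is
    unambiguous (default 2.1 um = centre of slice 10 at 0.2 um spacing).
    """

    n_slices: int = 48
    z_step: float = 0.2               # um
    xy_shape: tuple = (24, 36)        # (ny, nx) pixels
    membrane_z: float = 2.1           # um
    membrane_width: float = 0.25      # um, Gaussian sigma of the focus peak
    glyx_height: float = 4.0          # um
    probe_distribution: str = "uniform"
    outer_z_lo: float = 0.0           # um above the membrane ("outer" only)
    compression: float = 1.0          # ("compressed" only), in (0, 1]
    conserve_mass: bool = True
    psf_sigma_z: float = 0.3          # um axial PSF sigma; 0 disables blur
    photon_gain: float = 200.0        # expected counts/pixel/slice (uniform)
    membrane_gain: float = 400.0
    nuclei_gain: float = 150.0
    reference_gain: float = 120.0     # free-dye level in the outside region
    read_noise_sd: float = 2.0        # a.u.
    shot_noise: bool = True
    bleach_per_slice: float = 1.0     # geometric decay factor in (0, 1]
    include_nuclei: bool = True
    include_reference: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_distribution not in PROBE_DISTRIBUTIONS:
            raise InvalidParameterError(
                f"unknown probe_distribution {self.probe_distribution!r}")
        if self.n_slices < 8 or self.z_step <= 0:
            raise InvalidParameterError("need n_slices >= 8 and z_step > 0")
        if not (0 < self.compression <= 1):
            raise InvalidParameterError("compression must be in (0, 1]")
        if not (0 < self.bleach_per_slice <= 1):
            raise InvalidParameterError("bleach_per_slice must be in (0, 1]")
        if self.glyx_height <= 0 or self.membrane_z < 0:
            raise InvalidParameterError("invalid glycocalyx geometry")
        if self.membrane_z + self.glyx_height > self.n_slices * self.z_step:
            raise InvalidParameterError(
                "glycocalyx extends beyond the top of the stack")
        if not (0 <= self.outer_z_lo < self.glyx_height):
            raise InvalidParameterError(
                "outer_z_lo must lie in [0, glyx_height)")

    @property
    def probe_interval(self) -> tuple[float, float]:
        """Continuous axial support [lo, hi] (um) of the probe density."""
        m, h = self.membrane_z, self.glyx_height
        if self.probe_distribution == "uniform":
            return m, m + h
        if self.probe_distribution == "outer":
            return m + self.outer_z_lo, m + h
        return m, m + self.compression * h


def cell_roi(spec: StackSpec) -> RoiMask:
    """Analysis region over the cell (left part of the field)."""
    ny, nx = spec.xy_shape
    mask = np.zeros((ny, nx), dtype=bool)
    split = _reference_split(spec)
    mask[:, :split] = True
    return RoiMask(mask, label="cell")


def outside_roi(spec: StackSpec) -> RoiMask:
    """Reference region outside the cell (free dye, right part of the field)."""
    if not spec.include_reference:
        raise InvalidParameterError("spec has no reference region")
    ny, nx = spec.xy_shape
    mask = np.zeros((ny, nx), dtype=bool)
    mask[:, _reference_split(spec):] = True
    return RoiMask(mask, label="outside")


def _reference_split(spec: StackSpec) -> int:
    ny, nx = spec.xy_shape
    return (2 * nx) // 3 if spec.include_reference else nx


# --------------------------------------------------------------------------
# stack generation
# --------------------------------------------------------------------------

def _slice_overlap(spec: StackSpec, lo: float, hi: float) -> np.ndarray:
    """Exact overlap (um) of each slice extent [k dz, (k+1) dz) with [lo, hi]."""
    dz = spec.z_step
    edges = np.arange(spec.n_slices + 1) * dz
    return np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo),
                   0.0, None)


def probe_expectation(spec: StackSpec) -> np.ndarray:
    """Noise-free expected per-pixel probe counts per slice (before bleach).

    Normalized so a uniform full-height layer yields ``photon_gain`` per
    slice; any mass-conserving redistribution keeps the summed expectation
    constant.
    """
    lo, hi = spec.probe_interval
    overlap = _slice_overlap(spec, lo, hi)
    density = spec.photon_gain * spec.glyx_height / (hi - lo)
    if spec.probe_distribution == "compressed" and not spec.conserve_mass:
        density = spec.photon_gain
    expected = density * overlap / spec.z_step
    if spec.psf_sigma_z > 0:
        expected = gaussian_filter1d(expected, spec.psf_sigma_z / spec.z_step,
                                     mode="constant", truncate=8.0)
    return expected


def gen_zstack(spec: StackSpec) -> ZStack:
    """Render one synthetic multichannel stack from its specification."""
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.xy_shape
    n = spec.n_slices
    dz = spec.z_step
    centers = (np.arange(n) + 0.5) * dz
    bleach = spec.bleach_per_slice ** np.arange(n)
    split = _reference_split(spec)

    probe_axial = probe_expectation(spec)
    membrane_axial = spec.membrane_gain * np.exp(
        -0.5 * ((centers - spec.membrane_z) / spec.membrane_width) ** 2)
    nuclei_axial = np.where(centers <= spec.membrane_z, spec.nuclei_gain, 0.0)

    def render(axial_cell: np.ndarray, axial_outside: float | np.ndarray = 0.0
               ) -> np.ndarray:
        expected = np.zeros((n, ny, nx))
        expected[:, :, :split] = axial_cell[:, None, None]
        if split < nx:
            expected[:, :, split:] = (np.broadcast_to(
                np.asarray(axial_outside, dtype=float), (n,))[:, None, None])
        expected *= bleach[:, None, None]
        if spec.shot_noise:
            img = rng.poisson(expected).astype(float)
        else:
            img = expected.copy()
        if spec.read_noise_sd > 0:
            img += rng.normal(0.0, spec.read_noise_sd, size=img.shape)
        return np.clip(img, 0.0, None)

    channels = {
        "membrane": render(membrane_axial),
        "probe": render(probe_axial,
                        spec.reference_gain if spec.include_reference else 0.0),
    }
    if spec.include_nuclei:
        channels["nuclei"] = render(nuclei_axial)

    metadata = {
        "generator": "glyx.synthetic.gen_zstack",
        "seed": spec.seed,
        "probe_distribution": spec.probe_distribution,
        "compression": spec.compression,
        "outer_z_lo": spec.outer_z_lo,
        "membrane_z": spec.membrane_z,
        "glyx_height": spec.glyx_height,
        "true_height": spec.probe_interval[1] - spec.probe_interval[0],
    }
    return ZStack(channels=channels, z_step=dz, metadata=metadata)


# --------------------------------------------------------------------------
# crowder series
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CollapseSeriesSpec:
    """A crowder titration: dose (mg/mL) mapped to a compression factor.

    ``compression_map`` must be non-increasing in dose (more crowder, more
    collapse); ``conserve_mass`` keeps the integrated probe intensity
    constant across doses before noise.
    """

    doses: tuple
    compression_map: Mapping[float, float]
    conserve_mass: bool = True
    washout: bool = True

    def __post_init__(self) -> None:
        if len(self.doses) < 1:
            raise InvalidParameterError("need at least one dose")
        cs = [self.compression_map[d] for d in self.doses]
        for c in cs:
            if not (0 < c <= 1):
                raise InvalidParameterError("compression factors must be in (0,1]")
        order = np.argsort(self.doses)
        if np.any(np.diff(np.asarray(cs)[order]) > 1e-12):
            raise InvalidParameterError(
                "compression must be non-increasing in dose")


@dataclass(frozen=True)
class CollapsePoint:
    dose: float
    condition: str                 # before | during | after
    stack: ZStack


def gen_collapse_series(base: StackSpec,
                        series: CollapseSeriesSpec) -> list[CollapsePoint]:
    """Stacks of a crowder titration plus an after-washout acquisition.

    Each dose renders the base layer compressed by ``compression_map[dose]``
    (mass conserved when requested); the washout stack regenerates the
    uncompressed layer with a fresh sub-seed, emulating the reversibility of
    the oncotic collapse.
    """
    points = []
    for i, dose in enumerate(series.doses):
        c = series.compression_map[dose]
        spec = replace(base, probe_distribution="compressed", compression=c,
                       conserve_mass=series.conserve_mass,
                       seed=_subseed(base.seed, i))
        condition = "before" if c >= 1.0 else "during"
        points.append(CollapsePoint(dose=float(dose), condition=condition,
                                    stack=gen_zstack(spec)))
    if series.washout:
        spec = replace(base, probe_distribution="compressed", compression=1.0,
                       conserve_mass=series.conserve_mass,
                       seed=_subseed(base.seed, len(series.doses)))
        points.append(CollapsePoint(dose=0.0, condition="after",
                                    stack=gen_zstack(spec)))
    return points


def gen_graft_series(base: StackSpec, doses: Sequence[float],
                     accessibility_map: Mapping[float, float]
                     ) -> list[tuple[float, ZStack]]:
    """Post-washout probe-redistribution stacks for a crowder titration.

    During grafting at compression ``c`` only the outer, solution-accessible
    part of the layer is reachable; after washout and re-extension the
    grafted probe therefore occupies the outer interval
    ``[(1 - c) * glyx_height, glyx_height]``.  ``c = 1`` (no crowder) gives a
    uniform distribution.  Suitable input for
    :func:`glyx.zstack.dose_response`.
    """
    out = []
    for i, dose in enumerate(doses):
        c = accessibility_map[dose]
        if not (0 < c <= 1):
            raise InvalidParameterError("accessibility factors must be in (0,1]")
        spec = replace(base, probe_distribution="outer",
                       outer_z_lo=(1.0 - c) * base.glyx_height,
                       compression=1.0, seed=_subseed(base.seed, 100 + i))
        out.append((float(dose), gen_zstack(spec)))
    return out


def _subseed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence(entropy=seed,
                                      spawn_key=(index,)).generate_state(1)[0]
               % (2 ** 31))


# --------------------------------------------------------------------------
# mobility and cytometry datasets
# --------------------------------------------------------------------------

def gen_mobility_dataset(
    glx: ek.GlycocalyxModel,
    electrolyte: ek.Electrolyte,
    scenario: str,
    molecules_grid: Sequence[float],
    noise_sd: float = 0.02,
    seed: int = 0,
    **curve_kwargs,
) -> pd.DataFrame:
    """Synthetic mobility measurements from the electrokinetic model.

    ``noise_sd`` is the relative measurement noise; the reported ``sd``
    column is ``noise_sd * |mobility|`` (floored at a 1e-6 relative level so
    weighted fits remain defined for noiseless data).
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    curve = ek.mobility_curve(glx, electrolyte, molecules_grid, scenario,
                              **curve_kwargs)
    mu = curve["mobility"].to_numpy()
    sd = np.maximum(noise_sd, 1e-6) * np.abs(mu)
    noisy = mu + rng.normal(0.0, noise_sd * np.abs(mu)) if noise_sd > 0 else mu
    return pd.DataFrame({
        "molecules_per_cell": curve["molecules_per_cell"],
        "mobility": noisy,
        "sd": sd,
    })


def gen_cytometry(
    mfi_true_by_group: Mapping[str, float],
    cv: float = 0.1,
    n_events: int = 10000,
    n_replicates: int = 5,
    seed: int = 0,
    replicate_cv: float = 0.0,
) -> pd.DataFrame:
    """Replicate MFI table from log-normal event intensity populations.

    Event intensities are log-normal with median equal to the group truth and
    coefficient of variation ``cv`` on the log scale; each replicate MFI is
    the median of ``n_events`` events.  ``replicate_cv`` optionally adds
    log-normal day-to-day variation of the group truth (0 by default).
    """
    if cv <= 0:
        raise InvalidParameterError("cv must be > 0")
    if n_events < 100:
        raise InvalidParameterError("n_events must be >= 100")
    for group, truth in mfi_true_by_group.items():
        if truth <= 0:
            raise InvalidParameterError(f"group {group!r} truth must be > 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv ** 2))
    sigma_rep = math.sqrt(math.log1p(replicate_cv ** 2)) if replicate_cv else 0.0
    rows = []
    for group, truth in mfi_true_by_group.items():
        for rep in range(n_replicates):
            mu_rep = math.log(truth)
            if sigma_rep > 0:
                mu_rep += rng.normal(0.0, sigma_rep)
            events = rng.lognormal(mu_rep, sigma, size=n_events)
            rows.append({"group": group, "replicate": rep,
                         "mfi": float(np.median(events))})
    return pd.DataFrame(rows)
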