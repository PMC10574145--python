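"""Ingestion, segmentation and normalization of force–extension curves.

A single-molecule force-spectroscopy retraction trace has three regions:
an initial adhesion peak (nonspecific tip–surface attraction at small
extension), the elastic stretch of the molecular bridge, and an abrupt
detachment where the force drops to baseline.  Only the stretch region
carries polymer elasticity.  Because every picked-up chain has a different
contour length, curves are made comparable by dividing extensions by the
extension interpolated at a high reference force (1500 pN by default,
where elasticity is backbone-dominated and environment-independent); the
normalized curves of one polymer then overlay onto a single master curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CurveFormatError",
    "ForceExtensionCurve",
    "CurveSegmentation",
    "NormalizedCurve",
    "load_curves",
    "write_curves",
    "segment_curve",
    "extension_at_force",
    "normalize_curve",
    "overlay_dispersion",
]


class CurveFormatError(ValueError):
    """Malformed curve file (message carries the offending line number)."""


@dataclass
class ForceExtensionCurve:
    """A raw force–extension curve in acquisition order.

    ``extension`` in nm, ``force`` in pN; ``metadata`` holds free-form
    string annotations (e.g. generator ground truth).
    """

    extension: np.ndarray
    force: np.ndarray
    curve_id: str = ""
    environment: str = ""
    pulling_velocity: float | None = None  # μm/s, informational
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.extension.shape != self.force.shape or self.extension.ndim != 1:
            raise ValueError("extension and force must be 1-D arrays of equal length")
        if self.extension.size < 10:
            raise ValueError("a curve needs at least 10 samples")
        if not (np.all(np.isfinite(self.extension)) and np.all(np.isfinite(self.force))):
            raise ValueError("curve samples must be finite")
        if not self.extension.max() > 0:
            raise ValueError("maximum extension must be positive")

    @property
    def n_samples(self) -> int:
        return self.extension.size


@dataclass
class CurveSegmentation:
    """Indices delimiting adhesion, stretch and detachment regions."""

    adhesion_end_index: int
    stretch_start_index: int
    detachment_index: int | None  # None ⇒ unruptured (no detachment found)
    baseline_force: float

    def __post_init__(self) -> None:
        if self.adhesion_end_index > self.stretch_start_index:
            raise ValueError("adhesion_end_index must be ≤ stretch_start_index")
        if self.detachment_index is not None and not self.stretch_start_index < self.detachment_index:
            raise ValueError("stretch_start_index must be < detachment_index")

    @property
    def ruptured(self) -> bool:
        return self.detachment_index is not None


@dataclass
class NormalizedCurve:
    """A stretch region rescaled so extension at the reference force is 1.

    Samples are stored monotonized (isotonic in force along the extension
    axis, constant-force runs averaged); forces lie in (0, reference_force].
    """

    extension: np.ndarray  # dimensionless
    force: np.ndarray  # pN
    reference_force: float = 1500.0
    curve_id: str = ""
    environment: str = ""

    def __post_init__(self) -> None:
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if np.any(self.force <= 0) or np.any(self.force > self.reference_force + 1e-9):
            raise ValueError("normalized-curve forces must lie in (0, reference_force]")
        z_ref = np.interp(self.reference_force, self.force, self.extension)
        if abs(z_ref - 1.0) > 1e-6:
            raise ValueError("interpolated extension at the reference force must equal 1")

    def extension_at(self, force_grid) -> np.ndarray:
        """Interpolated normalized extension at the given forces."""
        grid = np.atleast_1d(np.asarray(force_grid, dtype=float))
        if grid.min() < self.force.min() or grid.max() > self.force.max():
            raise ValueError(
                f"force grid [{grid.min():g}, {grid.max():g}] outside curve "
                f"{self.curve_id!r} range [{self.force.min():g}, {self.force.max():g}]"
            )
        return np.interp(grid, self.force, self.extension)


# ---------------------------------------------------------------------------
# TSV dialect: '#key: value' metadata lines, a header 'extension_nm\tforce_pN',
# float rows; blank lines separate curves.
# ---------------------------------------------------------------------------

_HEADER = "extension_nm\tforce_pN"


def write_curves(curves: list[ForceExtensionCurve], path) -> None:
    """Write curves in the package TSV dialect (round-trips with load_curves)."""
    lines: list[str] = []
    for curve in curves:
        lines.append(f"#id: {curve.curve_id}")
        if curve.environment:
            lines.append(f"#environment: {curve.environment}")
        if curve.pulling_velocity is not None:
            lines.append(f"#pulling_velocity_um_s: {curve.pulling_velocity!r}")
        for key, value in curve.metadata.items():
            lines.append(f"#{key}: {value}")
        lines.append(_HEADER)
        for x, f in zip(curve.extension, curve.force):
            lines.append(f"{float(x)!r}\t{float(f)!r}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def load_curves(path) -> list[ForceExtensionCurve]:
    """Load curves from a TSV file in the package dialect.

    One curve per blank-line-delimited block; '#key: value' lines become
    metadata ('id', 'environment' and 'pulling_velocity_um_s' are mapped to
    the dedicated fields).  Malformed rows raise :class:`CurveFormatError`
    naming the line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    curves: list[ForceExtensionCurve] = []
    meta: dict = {}
    rows: list[tuple[float, float]] = []
    saw_header = False

    def flush(lineno: int) -> None:
        nonlocal meta, rows, saw_header
        if not rows and not meta:
            saw_header = False
            return
        if not saw_header:
            raise CurveFormatError(f"line {lineno}: curve block lacks the '{_HEADER}' header")
        curve_id = meta.pop("id", f"curve_{len(curves):03d}")
        environment = meta.pop("environment", "")
        velocity = meta.pop("pulling_velocity_um_s", None)
        arr = np.asarray(rows, dtype=float)
        curves.append(
            ForceExtensionCurve(
                extension=arr[:, 0],
                force=arr[:, 1],
                curve_id=str(curve_id),
                environment=str(environment),
                pulling_velocity=None if velocity is None else float(velocity),
                metadata=meta,
            )
        )
        meta, rows, saw_header = {}, [], False

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            flush(lineno)
            continue
        if line.startswith("#"):
            if ":" not in line:
                raise CurveFormatError(f"line {lineno}: metadata line must be '#key: value'")
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            continue
        if line == _HEADER:
            saw_header = True
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise CurveFormatError(f"line {lineno}: expected two tab-separated columns")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise CurveFormatError(f"line {lineno}: non-numeric value ({exc})") from exc
    flush(lineno + 1 if "lineno" in locals() else 1)
    if not curves:
        raise CurveFormatError("file contains no curve blocks")
    return curves


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def segment_curve(
    curve: ForceExtensionCurve,
    baseline_window: int = 20,
    drop_fraction: float = 0.8,
    adhesion_window: float = 8.0,
    min_peak_force: float = 50.0,
    spike_min_force: float = 25.0,
) -> CurveSegmentation:
    """Locate the adhesion peak, stretch region and detachment of a curve.

    Parameters
    ----------
    baseline_window:
        Number of samples after the adhesion region used to estimate the
        baseline force.
    drop_fraction:
        A force fall of at least this fraction of the running maximum
        within a 3-sample window marks detachment (rupture is abrupt).
    adhesion_window:
        Extension span (nm, from the first sample) searched for the
        adhesion spike.
    min_peak_force:
        Minimum global peak force (pN) for detachment detection; flat
        traces are flagged unruptured.
    spike_min_force:
        Minimum spike height (pN) for an adhesion peak to be recognized.

    The adhesion region ends at the force valley between the spike peak
    and the global force maximum — on noiseless traces this is the sample
    where the spike has decayed back onto the underlying elastic curve.
    """
    f = curve.force
    n = f.size
    gmax = int(np.argmax(f))

    # detachment: abrupt (≤ 3 samples) fall by ≥ drop_fraction of running max
    detachment: int | None = None
    if f[gmax] >= min_peak_force:
        running_max = f[gmax]
        for j in range(gmax + 1, n):
            window_max = max(running_max, float(np.max(f[max(j - 3, gmax) : j])))
            if f[j] <= (1.0 - drop_fraction) * window_max:
                detachment = j
                break

    # adhesion spike within the initial extension window, before the global max
    x0 = curve.extension[0]
    k = int(np.searchsorted(curve.extension, x0 + adhesion_window))
    k = min(max(k, 1), max(gmax, 1))
    adhesion_end = 0
    if k > 1:
        spike_peak = int(np.argmax(f[:k]))
        if f[spike_peak] >= spike_min_force and spike_peak < gmax:
            valley = spike_peak + int(np.argmin(f[spike_peak : gmax + 1]))
            # a genuine adhesion spike decays well below its peak before the
            # elastic rise; a monotone rise has no valley and no spike
            if f[valley] < 0.5 * f[spike_peak]:
                adhesion_end = valley

    stretch_start = adhesion_end
    stop = detachment if detachment is not None else n
    baseline = float(np.median(f[stretch_start : min(stretch_start + baseline_window, stop)]))
    return CurveSegmentation(
        adhesion_end_index=adhesion_end,
        stretch_start_index=stretch_start,
        detachment_index=detachment,
        baseline_force=baseline,
    )


def _monotone_stretch(curve: ForceExtensionCurve, segmentation: CurveSegmentation):
    """Monotonized stretch-region samples for force → extension interpolation.

    Extension is the noise-free coordinate of a retraction trace (the
    piezo ramp), so retrograde force samples are resolved by isotonic
    regression of force on extension rather than by re-sorting: re-sorting
    noisy forces distorts the flat low-force region and biases the
    downstream fit.  PAVA blocks of constant force are collapsed to their
    mean extension, yielding strictly increasing forces.
    """
    from scipy.optimize import isotonic_regression

    stop = segmentation.detachment_index
    sl = slice(segmentation.stretch_start_index, stop)
    force = curve.force[sl]
    ext = curve.extension[sl]
    order = np.argsort(ext, kind="stable")  # acquisition order is already sorted
    force, ext = force[order], ext[order]
    force = np.asarray(isotonic_regression(force).x)
    uniq, inverse = np.unique(force, return_inverse=True)
    if uniq.size != force.size:
        ext = np.bincount(inverse, weights=ext) / np.bincount(inverse)
        force = uniq
    return ext, force


def extension_at_force(
    curve: ForceExtensionCurve,
    segmentation: CurveSegmentation,
    target_force: float,
) -> float:
    """Extension (nm) at ``target_force`` by linear interpolation.

    Interpolation is linear in force → extension on the isotonically
    monotonized stretch region.  A target outside the covered force range
    raises ``ValueError``.
    """
    ext, force = _monotone_stretch(curve, segmentation)
    if force.size < 2:
        raise ValueError("stretch region too short for interpolation")
    if not force.min() <= target_force <= force.max():
        raise ValueError(
            f"target force {target_force:g} pN outside stretch range "
            f"[{force.min():g}, {force.max():g}] of curve {curve.curve_id!r}"
        )
    return float(np.interp(target_force, force, ext))


def normalize_curve(
    curve: ForceExtensionCurve,
    segmentation: CurveSegmentation,
    reference_force: float = 1500.0,
) -> NormalizedCurve:
    """Rescale the stretch region by its extension at ``reference_force``.

    The adhesion region is excluded; samples with non-positive force
    (baseline noise) or force above the reference are dropped.  The exact
    point (1, reference_force) is appended when not already sampled so the
    normalization invariant holds by construction.
    """
    x_ref = extension_at_force(curve, segmentation, reference_force)
    ext, force = _monotone_stretch(curve, segmentation)
    keep = (force > 0) & (force <= reference_force)
    ext, force = ext[keep] / x_ref, force[keep]
    if force.size == 0 or force[-1] < reference_force:
        ext = np.append(ext, 1.0)
        force = np.append(force, reference_force)
    return NormalizedCurve(
        extension=ext,
        force=force,
        reference_force=reference_force,
        curve_id=curve.curve_id,
        environment=curve.environment,
    )


def overlay_dispersion(curves: list[NormalizedCurve], force_grid) -> float:
    """RMS across-curve spread of normalized extension over a force grid.

    For each grid force the standard deviation of the interpolated
    normalized extension across curves is taken; the root-mean-square of
    those standard deviations is returned.  Identical curves give exactly
    0; curves from different elastic parameters give a strictly larger
    value than replicate noise does.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves to measure overlay dispersion")
    grid = np.asarray(force_grid, dtype=float)
    z = np.vstack([c.extension_at(grid) for c in curves])
    std = z.std(axis=0, ddof=0)
    return float(np.sqrt(np.mean(std**2)))
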