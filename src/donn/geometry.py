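"""Spatial oscillator layouts: spherical-shell and rectangular-grid layers.

To give the oscillator reservoir a cortical geometry, oscillators are placed
inside a "cortical layer" (a hollow spherical shell, or a rectangular grid of
stacked layers) beneath an "electrode layer" of labelled recording sites.
Connectivity is purely distance-based:

* an oscillator contributes to an electrode iff their Euclidean distance is
  below the assignment threshold ``xi1`` (strict inequality);
* two oscillators are laterally connected iff their distance is below
  ``xi2``, so long-range lateral connections never occur.  Newly connected
  pairs start with lateral magnitude ``A = 0.001``.

Defaults mirror the reference configuration: 1,000 oscillators in a shell
between 70 and 75 mm under electrodes at 85 mm, ``xi1 = 32`` mm,
``xi2 = 10`` mm; the rectangular grid holds 18 x 18 x 3 = 972 oscillators at
10 mm spacing.  Electrode montages are delimited-text tables (label,
theta_deg, phi_deg, r_mm); two montages ship with the package and any
user-provided file in the same dialect can replace them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .dynamics import LateralCoupling
from .errors import InputError
from .readout import HiddenReadout, hidden_forward, init_hidden_readout, train_hidden

__all__ = [
    "GeometryModel",
    "sph_to_cart",
    "load_montage",
    "build_spherical_shell",
    "build_rect_grid",
    "shared_oscillator_counts",
    "lateral_coupling_from_geometry",
    "MultiElectrodeReadout",
    "build_multi_electrode_model",
    "BUILTIN_MONTAGES",
]

BUILTIN_MONTAGES = ("1020_19", "frontocentral_8")


def sph_to_cart(theta_deg, phi_deg, r_mm):
    """EEG-cap spherical (azimuth theta, elevation phi, degrees) to Cartesian.

    ``x = r cos(phi) cos(theta), y = r cos(phi) sin(theta), z = r sin(phi)``.
    Vectorized over array inputs.
    """
    th = np.radians(np.asarray(theta_deg, dtype=float))
    ph = np.radians(np.asarray(phi_deg, dtype=float))
    r = np.asarray(r_mm, dtype=float)
    if np.any(r <= 0):
        raise InputError("radius must be positive")
    return (
        r * np.cos(ph) * np.cos(th),
        r * np.cos(ph) * np.sin(th),
        r * np.sin(ph),
    )


def load_montage(source: str | Path) -> tuple[list[str], np.ndarray]:
    """Load an electrode montage; returns (labels, xyz in mm).

    ``source`` is a built-in name (one of :data:`BUILTIN_MONTAGES`) or a path
    to a delimited-text file with columns label, theta_deg, phi_deg, r_mm.
    """
    if isinstance(source, str) and source in BUILTIN_MONTAGES:
        ref = resources.files("donn.data") / f"montage_{source}.tsv"
        with resources.as_file(ref) as path:
            df = pd.read_csv(path, sep="\t")
    else:
        path = Path(source)
        if not path.exists():
            raise InputError(
                f"montage {source!r} is neither a built-in name "
                f"{BUILTIN_MONTAGES} nor an existing file"
            )
        df = pd.read_csv(path, sep=None, engine="python")
    needed = {"label", "theta_deg", "phi_deg", "r_mm"}
    if not needed.issubset(df.columns):
        raise InputError(f"montage file must have columns {sorted(needed)}")
    x, y, z = sph_to_cart(df["theta_deg"], df["phi_deg"], df["r_mm"])
    return list(df["label"].astype(str)), np.column_stack([x, y, z])


@dataclass
class GeometryModel:
    """Oscillator/electrode coordinates plus the two distance-threshold masks."""

    osc_xyz: np.ndarray
    elec_xyz: np.ndarray
    elec_labels: list[str]
    assign_mask: np.ndarray
    lateral_mask: np.ndarray
    xi1: float
    xi2: float
    meta: dict = field(default_factory=dict)

    @property
    def n_osc(self) -> int:
        return self.osc_xyz.shape[0]

    @property
    def n_elec(self) -> int:
        return self.elec_xyz.shape[0]


def _masks(osc_xyz, elec_xyz, xi1, xi2):
    d1 = cdist(elec_xyz, osc_xyz)
    assign = d1 < xi1
    dij = cdist(osc_xyz, osc_xyz)
    lateral = dij < xi2
    np.fill_diagonal(lateral, False)
    return assign, lateral


def _warn_empty(assign, labels):
    empty = np.flatnonzero(~assign.any(axis=1))
    if empty.size:
        names = [labels[i] for i in empty]
        warnings.warn(
            f"electrode(s) {names} have no assigned oscillators", stacklevel=3
        )


def build_spherical_shell(
    n_osc: int = 1000,
    r_inner: float = 70.0,
    r_outer: float = 75.0,
    electrode_montage: str | Path = "frontocentral_8",
    seed: int = 0,
    xi1: float = 32.0,
    xi2: float = 10.0,
) -> GeometryModel:
    """Uniformly sample oscillators in a spherical shell under a montage.

    Sampling is uniform in *volume*: directions are isotropic and radii
    follow the inverse-CDF ``(r_in^3 + u (r_out^3 - r_in^3))^(1/3)``; fully
    reproducible from the seed.  Electrodes with no oscillator inside
    ``xi1`` trigger a warning, not an error (unequal assignment is expected
    on curved geometry).
    """
    labels, elec_xyz = load_montage(electrode_montage)
    r_elec = float(np.min(np.linalg.norm(elec_xyz, axis=1)))
    if not (0 < r_inner < r_outer < r_elec):
        raise InputError(
            f"need 0 < r_inner < r_outer < electrode radius ({r_elec:.1f} mm)"
        )
    rng = np.random.default_rng(seed)
    vec = rng.standard_normal((n_osc, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    u = rng.uniform(0.0, 1.0, n_osc)
    radius = np.cbrt(r_inner**3 + u * (r_outer**3 - r_inner**3))
    osc_xyz = vec * radius[:, None]
    assign, lateral = _masks(osc_xyz, elec_xyz, xi1, xi2)
    _warn_empty(assign, labels)
    return GeometryModel(
        osc_xyz, elec_xyz, labels, assign, lateral, xi1, xi2,
        {"shape": "sphere", "r_inner": r_inner, "r_outer": r_outer, "seed": seed},
    )


def build_rect_grid(
    nx: int = 18,
    ny: int = 18,
    n_layers: int = 3,
    spacing: float = 10.0,
    electrode_rows: list[tuple[str, float, float]] | None = None,
    clearance: float = 12.0,
    xi1: float = 32.0,
    xi2: float = 10.0,
) -> GeometryModel:
    """Rectangular grid of oscillators with coplanar electrodes above it.

    One oscillator per lattice unit over ``n_layers`` stacked planes.
    ``electrode_rows`` is a list of ``(label, x_mm, y_mm)`` placed in a plane
    ``clearance`` mm above the top layer; by default 8 electrodes form a 2x4
    grid over the centre of the lattice.
    """
    if spacing <= 0:
        raise InputError("grid spacing must be positive")
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing
    zs = np.arange(n_layers) * spacing
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    osc_xyz = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    if electrode_rows is None:
        cx = xs.mean()
        cy = ys.mean()
        dx = spacing * 4
        dy = spacing * 3
        electrode_rows = [
            (f"E{i + 1}", cx + (c - 1.5) * dx, cy + (r2 - 0.5) * dy)
            for i, (r2, c) in enumerate((r2, c) for r2 in range(2) for c in range(4))
        ]
    labels = [str(l) for l, _, _ in electrode_rows]
    z_e = zs.max() + clearance
    elec_xyz = np.array([[x, y, z_e] for _, x, y in electrode_rows], dtype=float)
    assign, lateral = _masks(osc_xyz, elec_xyz, xi1, xi2)
    _warn_empty(assign, labels)
    return GeometryModel(
        osc_xyz, elec_xyz, labels, assign, lateral, xi1, xi2,
        {"shape": "grid", "nx": nx, "ny": ny, "n_layers": n_layers,
         "spacing": spacing},
    )


def shared_oscillator_counts(geom: GeometryModel) -> np.ndarray:
    """Electrode-pair shared-oscillator counts.

    Entry (a, b) is the number of oscillators assigned to both electrodes;
    the diagonal holds per-electrode totals.  Symmetric by construction.
    """
    a = geom.assign_mask.astype(int)
    return a @ a.T


def lateral_coupling_from_geometry(
    geom: GeometryModel,
    A0: float = 0.001,
    scheme: str = "power",
    xi_w: float = 1e-3,
    tau_w: float = 1.0,
) -> LateralCoupling:
    """Lateral coupling restricted to the geometry's distance mask,
    initialized at magnitude ``A0`` with zero angles."""
    mask = geom.lateral_mask.copy()
    A = np.where(mask, A0, 0.0)
    return LateralCoupling(A, np.zeros_like(A), mask, scheme, xi_w, tau_w)


@dataclass
class MultiElectrodeReadout:
    """One hidden-layer readout per electrode over its assigned oscillators.

    Oscillators assigned to several electrodes drive several readouts;
    first-layer weights for unassigned oscillators do not exist (they are
    structurally zero).  Electrodes with no assigned oscillators get a
    constant-zero stub and are listed in ``stubs``.
    """

    readouts: list[HiddenReadout | None]
    osc_indices: list[np.ndarray]
    labels: list[str]
    n_osc: int

    @property
    def stubs(self) -> list[str]:
        return [l for l, r in zip(self.labels, self.readouts) if r is None]

    def forward(self, theta: np.ndarray) -> np.ndarray:
        th = np.atleast_2d(np.asarray(theta, dtype=float))
        out = np.zeros((th.shape[0], len(self.readouts)))
        for e, (ro, idx) in enumerate(zip(self.readouts, self.osc_indices)):
            if ro is not None:
                out[:, e] = hidden_forward(ro, th[:, idx])[:, 0]
        return out if np.asarray(theta).ndim == 2 else out[0]

    def train(self, theta_timeseries: np.ndarray, target: np.ndarray,
              epochs: int | None = None) -> "MultiElectrodeReadout":
        th = np.atleast_2d(np.asarray(theta_timeseries, dtype=float))
        yd = np.atleast_2d(np.asarray(target, dtype=float))
        if yd.shape[1] != len(self.readouts):
            raise InputError(
                f"target has {yd.shape[1]} channels for {len(self.readouts)} electrodes"
            )
        new = []
        for e, (ro, idx) in enumerate(zip(self.readouts, self.osc_indices)):
            if ro is None:
                new.append(None)
                continue
            new.append(train_hidden(ro, th[:, idx], yd[:, [e]], epochs=epochs))
        return MultiElectrodeReadout(new, self.osc_indices, self.labels, self.n_osc)


def build_multi_electrode_model(
    geom: GeometryModel,
    n_hidden_per_electrode: int = 100,
    seed: int = 0,
    **hidden_kw,
) -> MultiElectrodeReadout:
    """Per-electrode hidden readouts wired to the geometry's assignment mask."""
    readouts: list[HiddenReadout | None] = []
    indices: list[np.ndarray] = []
    for e in range(geom.n_elec):
        idx = np.flatnonzero(geom.assign_mask[e])
        indices.append(idx)
        if idx.size == 0:
            warnings.warn(
                f"electrode {geom.elec_labels[e]!r} has no oscillators; "
                "its readout is a constant-zero stub"
            )
            readouts.append(None)
            continue
        readouts.append(
            init_hidden_readout(1, idx.size, n_hidden_per_electrode,
                                seed + e, **hidden_kw)
        )
    return MultiElectrodeReadout(readouts, indices, list(geom.elec_labels), geom.n_osc)
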