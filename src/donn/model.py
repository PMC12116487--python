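"""Model archives: lossless, versioned persistence of trained networks.

A trained model bundles the oscillator bank (omega, r, theta), the lateral
coupling (A, phi, mask, scheme), the stage-1 real weights, one readout
(complex linear, hidden-layer, or per-electrode), optional geometry, the
configuration and the seed.  Archives are NumPy ``.npz`` files with a JSON
metadata entry, a format version and a SHA-256 content checksum; loading a
newer major version or a corrupted file raises a typed error.  Save/load is
bit-exact, so a reloaded model generates the identical continuation.
"""

from __future__ import annotations

import hashlib
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dynamics import LateralCoupling, OscillatorBank
from .errors import IntegrityError
from .generation import run_free
from .geometry import GeometryModel, MultiElectrodeReadout
from .readout import ComplexLinearReadout, HiddenReadout
from .signal import MultichannelSignal

__all__ = ["TrainedModel", "save_model", "load_model", "FORMAT_VERSION"]

FORMAT_VERSION = (1, 0)  # (major, minor)


@dataclass
class TrainedModel:
    """Everything needed to reproduce reconstruction and generation."""

    bank: OscillatorBank
    coupling: LateralCoupling
    alpha: np.ndarray
    readout: ComplexLinearReadout | HiddenReadout | MultiElectrodeReadout
    fs: float
    labels: list[str]
    seed: int
    config: dict = field(default_factory=dict)
    geometry: GeometryModel | None = None

    def generate(self, seconds: float, integrator: str = "rk4") -> MultichannelSignal:
        """Free-run the model from its stored state for ``seconds``."""
        sig, _ = run_free(
            self.bank, self.coupling, self.readout, seconds, self.fs,
            integrator=integrator, labels=list(self.labels),
        )
        return sig


def _checksum(arrays: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for key in sorted(arrays):
        h.update(key.encode())
        h.update(np.ascontiguousarray(arrays[key]).tobytes())
    return h.hexdigest()


def _readout_arrays(readout) -> tuple[str, dict, dict]:
    if isinstance(readout, ComplexLinearReadout):
        arrays = {"ro_K": readout.K, "ro_xi": readout.xi}
        extra = {"eta_K": readout.eta_K, "eta_xi": readout.eta_xi,
                 "epochs": readout.epochs}
        return "linear", arrays, extra
    if isinstance(readout, HiddenReadout):
        arrays = {
            "ro_Win_re": readout.W_in.real, "ro_Win_im": readout.W_in.imag,
            "ro_bh": readout.b_h, "ro_Wout": readout.W_out, "ro_bo": readout.b_o,
            "ro_scale": readout.output_scale,
        }
        extra = {
            "output_activation": readout.output_activation,
            "eta_h": readout.eta_h, "eta_o": readout.eta_o,
            "epochs": readout.epochs, "momentum": readout.momentum,
            "complex_input": readout.complex_input,
            "optimizer": readout.optimizer,
        }
        return "hidden", arrays, extra
    if isinstance(readout, MultiElectrodeReadout):
        arrays = {}
        per = []
        for e, (ro, idx) in enumerate(zip(readout.readouts, readout.osc_indices)):
            arrays[f"me{e}_idx"] = np.asarray(idx, dtype=np.int64)
            if ro is None:
                per.append(None)
                continue
            arrays[f"me{e}_Win_re"] = ro.W_in.real
            arrays[f"me{e}_Win_im"] = ro.W_in.imag
            arrays[f"me{e}_bh"] = ro.b_h
            arrays[f"me{e}_Wout"] = ro.W_out
            arrays[f"me{e}_bo"] = ro.b_o
            arrays[f"me{e}_scale"] = ro.output_scale
            per.append({
                "output_activation": ro.output_activation, "eta_h": ro.eta_h,
                "eta_o": ro.eta_o, "epochs": ro.epochs, "momentum": ro.momentum,
                "complex_input": ro.complex_input, "optimizer": ro.optimizer,
            })
        extra = {"labels": readout.labels, "n_osc": readout.n_osc, "per": per}
        return "multi", arrays, extra
    raise IntegrityError(f"cannot serialize readout of type {type(readout)!r}")


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write a versioned, checksummed archive of the trained model."""
    arrays = {
        "omega": model.bank.omega, "r": model.bank.r, "theta": model.bank.theta,
        "A": model.coupling.A, "phi": model.coupling.phi,
        "mask": model.coupling.mask, "alpha": np.asarray(model.alpha, dtype=float),
    }
    kind, ro_arrays, ro_extra = _readout_arrays(model.readout)
    arrays.update(ro_arrays)
    if model.geometry is not None:
        g = model.geometry
        arrays.update({
            "geo_osc": g.osc_xyz, "geo_elec": g.elec_xyz,
            "geo_assign": g.assign_mask, "geo_lateral": g.lateral_mask,
        })
    meta = {
        "format_version": list(FORMAT_VERSION),
        "readout_kind": kind,
        "readout_extra": ro_extra,
        "bank": {"mu": model.bank.mu, "beta": model.bank.beta},
        "coupling": {"scheme": model.coupling.scheme,
                     "xi_w": model.coupling.xi_w, "tau_w": model.coupling.tau_w},
        "fs": model.fs,
        "labels": model.labels,
        "seed": model.seed,
        "config": model.config,
        "geometry": None if model.geometry is None else {
            "labels": model.geometry.elec_labels,
            "xi1": model.geometry.xi1, "xi2": model.geometry.xi2,
            "meta": model.geometry.meta,
        },
        "checksum": _checksum(arrays),
    }
    np.savez(
        Path(path),
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **arrays,
    )


def load_model(path: str | Path) -> TrainedModel:
    """Read an archive written by :func:`save_model`, verifying integrity."""
    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as npz:
            data = {k: npz[k] for k in npz.files}
    except (OSError, zipfile.BadZipFile, ValueError, KeyError) as exc:
        raise IntegrityError(f"cannot read model archive {path}: {exc}") from exc
    if "__meta__" not in data:
        raise IntegrityError(f"{path} is not a model archive (missing metadata)")
    meta = json.loads(bytes(data.pop("__meta__")).decode())
    major = meta.get("format_version", [0])[0]
    if major > FORMAT_VERSION[0]:
        raise IntegrityError(
            f"archive format {meta['format_version']} is newer than supported "
            f"{list(FORMAT_VERSION)}"
        )
    if meta["checksum"] != _checksum(data):
        raise IntegrityError(f"checksum mismatch in {path}: archive corrupted")
    bank = OscillatorBank(
        data["omega"], data["r"], data["theta"],
        meta["bank"]["mu"], meta["bank"]["beta"],
    )
    cp = meta["coupling"]
    coupling = LateralCoupling(
        data["A"], data["phi"], data["mask"], cp["scheme"], cp["xi_w"], cp["tau_w"]
    )
    kind = meta["readout_kind"]
    extra = meta["readout_extra"]
    if kind == "linear":
        readout = ComplexLinearReadout(
            data["ro_K"], data["ro_xi"], extra["eta_K"], extra["eta_xi"],
            extra["epochs"],
        )
    elif kind == "hidden":
        readout = HiddenReadout(
            data["ro_Win_re"] + 1j * data["ro_Win_im"], data["ro_bh"],
            data["ro_Wout"], data["ro_bo"], extra["output_activation"],
            extra["eta_h"], extra["eta_o"], extra["epochs"], extra["momentum"],
            data["ro_scale"], extra["complex_input"], extra.get("optimizer", "sgd"),
        )
    elif kind == "multi":
        ros: list[HiddenReadout | None] = []
        idxs = []
        for e, per in enumerate(extra["per"]):
            idxs.append(data[f"me{e}_idx"])
            if per is None:
                ros.append(None)
                continue
            ros.append(HiddenReadout(
                data[f"me{e}_Win_re"] + 1j * data[f"me{e}_Win_im"],
                data[f"me{e}_bh"], data[f"me{e}_Wout"], data[f"me{e}_bo"],
                per["output_activation"], per["eta_h"], per["eta_o"],
                per["epochs"], per["momentum"], data[f"me{e}_scale"],
                per["complex_input"], per.get("optimizer", "sgd"),
            ))
        readout = MultiElectrodeReadout(ros, idxs, extra["labels"], extra["n_osc"])
    else:
        raise IntegrityError(f"unknown readout kind {kind!r} in archive")
    geometry = None
    if meta.get("geometry") is not None:
        gm = meta["geometry"]
        geometry = GeometryModel(
            data["geo_osc"], data["geo_elec"], gm["labels"],
            data["geo_assign"], data["geo_lateral"], gm["xi1"], gm["xi2"],
            gm.get("meta", {}),
        )
    return TrainedModel(
        bank, coupling, data["alpha"], readout, meta["fs"], meta["labels"],
        meta["seed"], meta.get("config", {}), geometry,
    )
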