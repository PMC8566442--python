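"""Reconstruction metrics and the cross-method comparison harness.

The central score is the coefficient of determination

    r^2 = 1 - sum_i (y_i - f_i)^2 / sum_i (y_i - ybar)^2

summed over *all* entries of a modality matrix (voxels x features), i.e.
the fraction of total variance a factorization's reconstruction
explains. ``compare_methods`` assembles per-method, per-modality r^2 and
MSE plus cross-correlation tables between linked components and
dictionary atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Any

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .dlsc import DictionaryModel
    from .linked_ica import LinkedDecomposition
    from .types import ModalityMatrix

__all__ = ["r_squared", "mse", "ReconstructionReport", "compare_methods"]


def r_squared(y: np.ndarray, f: np.ndarray) -> float:
    """Fraction of total variance of ``y`` explained by reconstruction ``f``."""
    y = np.asarray(y, dtype=float).ravel()
    f = np.asarray(f, dtype=float).ravel()
    if y.shape != f.shape:
        raise ValueError("y and f must have the same number of entries")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r_squared undefined for constant y")
    return 1.0 - float(np.sum((y - f) ** 2)) / ss_tot


def mse(y: np.ndarray, f: np.ndarray) -> float:
    """Mean squared residual over all entries."""
    y = np.asarray(y, dtype=float).ravel()
    f = np.asarray(f, dtype=float).ravel()
    if y.shape != f.shape:
        raise ValueError("y and f must have the same number of entries")
    return float(np.mean((y - f) ** 2))


@dataclass
class ReconstructionReport:
    method_name: str
    r2: dict[str, float] = field(default_factory=dict)     # modality -> r^2
    mse: dict[str, float] = field(default_factory=dict)    # modality -> mse

    def as_dict(self) -> dict[str, Any]:
        return {"method": self.method_name, "r2": dict(self.r2), "mse": dict(self.mse)}


def compare_methods(
    linked: "LinkedDecomposition",
    dicts: dict[str, "DictionaryModel"],
    modalities: list["ModalityMatrix"],
    alpha: float = 0.004,
) -> dict[str, Any]:
    """Reconstruction accuracy of linked ICA vs DLSC fits, plus spatial
    cross-correlations between linked components and each dictionary.

    ``dicts`` maps a method label (e.g. ``"exclusive-gene"``, ``"concat"``)
    to a fitted dictionary. r^2/MSE are computed on the z-scored matrices
    (the scale every method was fit on) and on the raw data.
    """
    from .components import cross_correlate  # local import to avoid a cycle

    names = [m.modality_name for m in modalities]
    if len(set(names)) != len(names):
        names = [f"{n}_{k}" for k, n in enumerate(names)]

    reports: dict[str, Any] = {"methods": {}, "cross_correlation": {}}

    rep = ReconstructionReport(method_name="linked_ica")
    for k, m in enumerate(modalities):
        recon_z = linked.reconstruct(k)
        recon_raw = linked.reconstruct(k, original_units=True)
        yz = _zscore_rows(m.values)
        rep.r2[names[k]] = r_squared(yz, recon_z)
        rep.mse[names[k]] = mse(yz, recon_z)
        rep.r2[names[k] + "_raw"] = r_squared(m.values, recon_raw)
        rep.mse[names[k] + "_raw"] = mse(m.values, recon_raw)
    reports["methods"]["linked_ica"] = rep

    for label, model in dicts.items():
        drep = ReconstructionReport(method_name=label)
        for k, m in enumerate(modalities):
            if not model.covers_modality(m.modality_name) and \
                    not model.covers_modality(names[k]):
                continue
            yz = _zscore_rows(m.values)
            if yz.shape[1] != model.atoms.shape[1]:
                raise ValueError(
                    f"dictionary {label!r} has {model.atoms.shape[1]} voxels, "
                    f"modality {names[k]!r} has {yz.shape[1]}"
                )
            recon = model.reconstruct(m.modality_name) \
                if model.covers_modality(m.modality_name) \
                else model.reconstruct(names[k])
            drep.r2[names[k]] = r_squared(yz, recon)
            drep.mse[names[k]] = mse(yz, recon)
        reports["methods"][label] = drep
        reports["cross_correlation"][label] = cross_correlate(
            linked.H, model.atoms, alpha=alpha
        )
    return reports


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (values - mu) / sd
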