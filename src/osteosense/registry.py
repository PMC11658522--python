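"""Versioned registry of tissue optical properties and channel defaults.

The registry ships as a JSON file inside the package and holds, per tissue
(cancellous / cortical bone) and per wavelength (940 / 1310 nm):

* the optical-property triple (mu_a, mu_s', g) in cm^-1,
* the optoelectronic channel defaults (laser power, coupling efficiencies,
  photodiode responsivity) and the reference collected fractions in permille.

A user-supplied JSON file with the same schema can be loaded instead, e.g.
to study candidate wavelengths whose properties are not shipped.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Any

__all__ = [
    "load_registry",
    "bone_optics",
    "channel_defaults",
    "reference_reflectance",
    "WAVELENGTHS_NM",
    "TISSUES",
]

WAVELENGTHS_NM = (940, 1310)
TISSUES = ("cancellous", "cortical")


@lru_cache(maxsize=8)
def _load(path: str | None) -> dict[str, Any]:
    if path is None:
        text = resources.files("osteosense.data").joinpath("properties.json").read_text()
    else:
        text = Path(path).read_text()
    reg = json.loads(text)
    if "tissues" not in reg or "channels" not in reg:
        raise ValueError("registry file must define 'tissues' and 'channels'")
    return reg


def load_registry(path: str | None = None) -> dict[str, Any]:
    """Return the full registry dict (shipped defaults if *path* is None)."""
    return _load(path)


def bone_optics(tissue: str, wavelength_nm: int, path: str | None = None):
    """Optical properties (:class:`~osteosense.optics.OpticalProperties`) for
    one tissue at one wavelength, in cm^-1."""
    from .optics import OpticalProperties

    reg = _load(path)
    try:
        entry = reg["tissues"][tissue][str(wavelength_nm)]
    except KeyError as exc:
        raise KeyError(
            f"no optical properties for tissue={tissue!r} at {wavelength_nm} nm; "
            f"available: {sorted(reg['tissues'])} x "
            f"{sorted(k for v in reg['tissues'].values() for k in v)}"
        ) from exc
    return OpticalProperties(entry["mu_a"], entry["mu_s_prime"], entry["g"])


def channel_defaults(wavelength_nm: int, path: str | None = None) -> dict[str, Any]:
    """Default laser / coupling / responsivity parameters for one channel."""
    reg = _load(path)
    try:
        return dict(reg["channels"][str(wavelength_nm)])
    except KeyError as exc:
        raise KeyError(f"no channel defaults for {wavelength_nm} nm") from exc


def reference_reflectance(tissue: str, wavelength_nm: int, path: str | None = None) -> float:
    """Reference collected fraction (dimensionless, not permille) for one
    tissue/wavelength cell, as estimated by the high-count transport runs."""
    ch = channel_defaults(wavelength_nm, path)
    try:
        return ch["r_tissue_permille"][tissue] * 1e-3
    except KeyError as exc:
        raise KeyError(f"no reference reflectance for {tissue!r}") from exc
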