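"""Optical power to photocurrent: the probe's detection chain.

The laser emits P_LD; butt-coupling into the emitter fiber keeps a fraction
eta_LD; the tissue returns the collected fraction R_tissue(lambda) to the
collector fiber; coupling onto the photodiode keeps eta_PD; the photodiode
converts watts to amps with its responsivity R_PD(lambda):

    P_in = P_LD * eta_LD * R_tissue(lambda) * eta_PD        [W]
    I_PD = P_in * R_PD(lambda) + I_dark                      [A]

With the design-table defaults (51.1 mW / 10.3 mW lasers, 30% couplings,
bone reflectances of 0.0955-0.152 permille, responsivities 0.62 / 0.91 A/W)
the four tissue x wavelength channels span roughly 81-433 nA.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .registry import TISSUES, WAVELENGTHS_NM, channel_defaults, reference_reflectance

__all__ = [
    "SignalChainParams",
    "ChannelSpec",
    "incident_power",
    "photocurrent",
    "photocurrent_table",
    "default_channels",
]


@dataclass(frozen=True)
class SignalChainParams:
    """Optoelectronic chain parameters for one laser/photodiode channel.

    ``p_ld`` is in watts; efficiencies are fractions in [0, 1]; ``r_pd`` in
    A/W; ``i_dark`` in amperes (defaults to 0: the datasheet value is not
    part of the design tables, it exists for noise studies); ``c_j`` is the
    photodiode junction capacitance in farads (metadata for the amplifier
    stability discussion, unused in the DC chain).
    """

    p_ld: float
    eta_ld: float = 0.30
    eta_pd: float = 0.30
    r_pd: float = 1.0
    i_dark: float = 0.0
    c_j: float = 60e-12

    def __post_init__(self) -> None:
        if self.p_ld < 0 or self.r_pd < 0:
            raise ValueError("p_ld and r_pd must be >= 0")
        if not (0 <= self.eta_ld <= 1 and 0 <= self.eta_pd <= 1):
            raise ValueError("coupling efficiencies must lie in [0, 1]")


@dataclass(frozen=True)
class ChannelSpec:
    """One tissue x wavelength cell: chain parameters plus the tissue
    reflectance feeding them (a fraction, not permille)."""

    wavelength_nm: int
    chain: SignalChainParams
    tissue_reflectance: float
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if not 0 <= self.tissue_reflectance <= 1:
            raise ValueError("tissue_reflectance must lie in [0, 1]")

    @property
    def current(self) -> float:
        c = self.chain
        return photocurrent(
            incident_power(c.p_ld, c.eta_ld, self.tissue_reflectance, c.eta_pd),
            c.r_pd, c.i_dark)


def incident_power(p_ld: float, eta_ld: float, r_tissue: float,
                   eta_pd: float) -> float:
    """Optical power reaching the photodiode surface, in watts."""
    if min(p_ld, eta_ld, r_tissue, eta_pd) < 0:
        raise ValueError("all factors must be >= 0")
    if max(eta_ld, eta_pd) > 1:
        raise ValueError("coupling efficiencies must be <= 1")
    return p_ld * eta_ld * r_tissue * eta_pd


def photocurrent(p_in: float, r_pd: float, i_dark: float = 0.0) -> float:
    """Photodiode output current in amperes: P_in * R_PD + I_dark."""
    if p_in < 0 or r_pd < 0:
        raise ValueError("p_in and r_pd must be >= 0")
    return p_in * r_pd + i_dark


def default_channel_params(wavelength_nm: int,
                           registry_path: str | None = None) -> SignalChainParams:
    """Shipped chain defaults for one wavelength (power in W, R_PD in A/W)."""
    ch = channel_defaults(wavelength_nm, registry_path)
    return SignalChainParams(p_ld=ch["p_ld_mw"] * 1e-3, eta_ld=ch["eta_ld"],
                             eta_pd=ch["eta_pd"], r_pd=ch["r_pd_a_per_w"])


def default_channels(registry_path: str | None = None,
                     eta_scale: float = 1.0) -> list[ChannelSpec]:
    """The four shipped tissue x wavelength channels.

    ``eta_scale`` multiplies both coupling efficiencies of every channel —
    handy for studying hardware whose couplings fall short of the 30%
    design estimate (the ratio classifier is invariant under a common
    scale).
    """
    specs = []
    for wl in WAVELENGTHS_NM:
        base = default_channel_params(wl, registry_path)
        chain = replace(base, eta_ld=base.eta_ld * eta_scale,
                        eta_pd=base.eta_pd * eta_scale)
        for tissue in TISSUES:
            specs.append(ChannelSpec(
                wavelength_nm=wl, chain=chain, tissue=tissue,
                tissue_reflectance=reference_reflectance(tissue, wl,
                                                         registry_path)))
    return specs


def photocurrent_table(channels: list[ChannelSpec]):
    """Per-channel photocurrents plus their (min, max) envelope.

    Returns ``(rows, (i_min, i_max))`` where each row is a dict with the
    channel identity and its current in amperes.
    """
    if not channels:
        raise ValueError("channel list must not be empty")
    rows = [{"wavelength_nm": ch.wavelength_nm, "tissue": ch.tissue,
             "tissue_reflectance": ch.tissue_reflectance,
             "current_a": ch.current} for ch in channels]
    currents = [r["current_a"] for r in rows]
    return rows, (min(currents), max(currents))
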