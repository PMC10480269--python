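"""Striped-card reflectance and laser-spot overlap model.

The moving platform carries a white card printed with dark bars; a laser
spot illuminates it.  As the card moves vertically through the fixed spot,
the reflected power is modulated by the bar pattern, encoding displacement
as intensity.

The card is modelled as a one-dimensional piecewise-constant reflectance
field along the travel axis: the stripes span the card width, so the
transverse dimension integrates out.  The circular spot reduces to a
1D weighting kernel over that axis -- the chord length of the disc for a
top-hat (uniform) beam, a Gaussian for a Gaussian beam -- and the reflected
fraction is the kernel-weighted average of the field.  Both kernels are
integrated analytically over each constant segment, so the result is exact
up to floating point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

__all__ = ["StripedCard", "LaserSpot", "reflectance_profile", "reflected_fraction"]

MM_PER_CM = 10.0


@dataclass
class StripedCard:
    """Reflectance field of the striped card, 1D along the travel axis.

    Positions are in mm, measured from the point of the card that faces the
    laser spot when the platform sits at mid-travel.  ``bar_center_offset``
    shifts the (center of the) dark-bar pattern away from that point; with
    several bars the pattern repeats with a pitch of two bar widths
    (alternating dark/light stripes of equal width).
    """

    bar_width: float = 2.0  # mm
    n_dark_bars: int = 1
    bar_center_offset: float = 0.0  # mm from the mid-travel position
    reflectance_white: float = 0.90
    reflectance_black: float = 0.05
    card_extent: float = 100.0  # mm, card spans +/- card_extent/2

    def __post_init__(self) -> None:
        if not (0.0 <= self.reflectance_black < self.reflectance_white <= 1.0):
            raise ValueError(
                "need 0 <= reflectance_black < reflectance_white <= 1, got "
                f"black={self.reflectance_black}, white={self.reflectance_white}"
            )
        if self.bar_width <= 0:
            raise ValueError(f"bar_width must be > 0, got {self.bar_width}")
        if self.n_dark_bars < 0:
            raise ValueError(f"n_dark_bars must be >= 0, got {self.n_dark_bars}")
        half = self.card_extent / 2.0
        for lo, hi in self.bar_intervals():
            if lo < -half or hi > half:
                raise ValueError(
                    f"dark bar [{lo}, {hi}] mm extends beyond the card "
                    f"(+/-{half} mm); shrink bar_center_offset or n_dark_bars"
                )

    def bar_intervals(self) -> list[tuple[float, float]]:
        """(low, high) position of every dark bar, in mm."""
        pitch = 2.0 * self.bar_width
        centers = [
            self.bar_center_offset + (i - (self.n_dark_bars - 1) / 2.0) * pitch
            for i in range(self.n_dark_bars)
        ]
        return [(c - self.bar_width / 2.0, c + self.bar_width / 2.0) for c in centers]


@dataclass
class LaserSpot:
    """Illumination footprint and spectral line of the laser.

    ``geometry_factor`` converts platform travel into spot travel across the
    card; it absorbs the small projection effect of the tilted illumination
    geometry (default 1.0 = spot moves with the card one-to-one).
    """

    diameter: float = 2.0  # mm on the card
    profile: str = "tophat"  # or "gaussian" (FWHM = diameter)
    center_wavelength: float = 632.8  # nm
    linewidth_fwhm: float = 1.5  # nm, as seen by the spectrometer
    power: float = 3.0  # mW
    geometry_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"diameter must be > 0, got {self.diameter}")
        if not (0.0 < self.geometry_factor <= 2.0):
            raise ValueError(
                f"geometry_factor must lie in (0, 2], got {self.geometry_factor}"
            )
        if self.center_wavelength <= 0:
            raise ValueError(
                f"center_wavelength must be > 0, got {self.center_wavelength}"
            )
        if self.profile not in ("tophat", "gaussian"):
            raise ValueError(f"profile must be 'tophat' or 'gaussian', got {self.profile!r}")


def reflectance_profile(card: StripedCard, position) -> np.ndarray | float:
    """Point reflectance of the card at ``position`` (mm).

    ``reflectance_black`` inside any dark bar, ``reflectance_white``
    elsewhere on the card, 0 beyond the card edges.  Accepts scalars or
    arrays.
    """
    pos = np.asarray(position, dtype=float)
    out = np.full(pos.shape, card.reflectance_white)
    for lo, hi in card.bar_intervals():
        out[(pos >= lo) & (pos <= hi)] = card.reflectance_black
    half = card.card_extent / 2.0
    out[(pos < -half) | (pos > half)] = 0.0
    return out if out.ndim else float(out)


def _field_edges(card: StripedCard) -> tuple[np.ndarray, np.ndarray]:
    """Breakpoints of the piecewise-constant field and the value per segment."""
    half = card.card_extent / 2.0
    edges = {-half, half}
    for lo, hi in card.bar_intervals():
        edges.update((lo, hi))
    edges = np.array(sorted(edges))
    mids = (edges[:-1] + edges[1:]) / 2.0
    values = np.asarray(reflectance_profile(card, mids), dtype=float)
    return edges, values


def _tophat_cdf(u: np.ndarray, radius: float) -> np.ndarray:
    """Cumulative chord-length weight of a disc of given radius, normalised."""
    uc = np.clip(u / radius, -1.0, 1.0)
    return (uc * np.sqrt(1.0 - uc**2) + np.arcsin(uc)) / math.pi + 0.5


def reflected_fraction(card: StripedCard, spot: LaserSpot, displacement) -> np.ndarray | float:
    """Fraction of the spot power reflected at a platform displacement (cm).

    The spot center sits at ``geometry_factor * displacement`` (converted to
    mm) on the card's travel axis; the return value is the spot-profile
    weighted average of :func:`reflectance_profile` over the footprint.
    Continuous in displacement and bounded by the field's extreme values.
    Accepts scalar or array displacement.
    """
    disp = np.asarray(displacement, dtype=float)
    centers = spot.geometry_factor * disp * MM_PER_CM
    edges, values = _field_edges(card)

    if spot.profile == "tophat":
        radius = spot.diameter / 2.0
        cdf = lambda u: _tophat_cdf(u, radius)  # noqa: E731
        lo_support, hi_support = -radius, radius
    else:
        sigma = spot.diameter / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        cdf = lambda u: ndtr(u / sigma)  # noqa: E731
        lo_support, hi_support = -np.inf, np.inf

    c = np.atleast_1d(centers)
    total = np.zeros(c.shape)
    # off-card segments carry reflectance 0, so only [edges[0], edges[-1]]
    # contributes; Gaussian tails beyond the card add nothing.
    prev = cdf(np.clip(edges[0] - c, lo_support, hi_support))
    for k in range(len(values)):
        cur = cdf(np.clip(edges[k + 1] - c, lo_support, hi_support))
        total += values[k] * (cur - prev)
        prev = cur
    return total.reshape(disp.shape) if disp.ndim else float(total[0])


def default_card_for(displacement_cm: float) -> StripedCard:
    """Card geometry used by the simulator for a given peak-to-peak travel.

    The card carries one wide dark band covering exactly the lower half of
    the travel range, with the black/white boundary at mid-travel.  The
    spot then sits on the dark band for one half of every cycle and on
    white for the other: a 50%-duty square modulation whose even
    harmonics cancel and whose strongest overtone (3f) is a third of the
    fundamental, so the dominant spectral line is the platform frequency
    itself for every waveform shape and phase.

    Narrow-bar geometries are far less favourable: a narrow bar crossed at
    fractional spacing alpha*T weights harmonic n by |cos(pi*n*alpha)|
    (alpha = 1/2 cancels f outright in favour of 2f, alpha = 1/3 doubles
    3f), and even a narrow bar at a turning point yields a near-impulsive
    dip train whose 2nd harmonic comes within a few percent of the
    fundamental at cm-scale travels.  Such cards remain expressible through
    :class:`StripedCard` directly.
    """
    half_travel_mm = displacement_cm * MM_PER_CM / 2.0
    return StripedCard(
        bar_width=half_travel_mm,
        bar_center_offset=-half_travel_mm / 2.0,
    )
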