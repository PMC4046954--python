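"""Binned prey fields built from a normalized biomass size spectrum.

The plankton prey of a fish larva (0.04–2 mm protists and copepods) are
discretised into 196 length bins of 0.01 mm.  A prey field is specified by
its total dry biomass ``b_total`` and a normalized size-spectrum slope
``s``: biomass density per unit body mass is assumed proportional to mˢ, so
the biomass in a bin is the analytic integral of mˢ across the bin's mass
range.  Individual prey dry mass follows a power law of length, m = a·lᵇ.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MG_M3_TO_UG_MM3, ModelConfig
from .errors import ValidationError

__all__ = ["PreyField", "length_to_mass", "build_spectrum", "explicit_field"]


@dataclass(frozen=True)
class PreyField:
    """A discretised prey field.

    All arrays have one entry per bin.  ``b`` is biomass concentration in
    µg mm⁻³, ``c = b/m`` is numeric concentration in mm⁻³, ``m`` is the
    individual dry mass at the bin centre in µg, lengths are mm.
    ``b_total`` is stored in the user-facing unit mg m⁻³.
    """

    l_center: np.ndarray
    l_lo: np.ndarray
    l_hi: np.ndarray
    m: np.ndarray
    m_lo: np.ndarray
    m_hi: np.ndarray
    b: np.ndarray
    c: np.ndarray
    b_total: float
    s: float

    @property
    def n_bins(self) -> int:
        return self.l_center.size

    def to_frame(self) -> pd.DataFrame:
        """Per-bin breakdown as a DataFrame (l_lo, l_hi, l_center, m, b, c)."""
        return pd.DataFrame(
            {
                "l_lo": self.l_lo,
                "l_hi": self.l_hi,
                "l_center": self.l_center,
                "m": self.m,
                "b": self.b,
                "c": self.c,
            }
        )

    def to_csv(self, path_or_buf=None):
        """Write the field as CSV with a ``#``-comment header carrying
        b_total (mg m⁻³) and s."""
        header = f"# b_total={self.b_total!r} s={self.s!r}\n"
        frame = self.to_frame()
        if path_or_buf is None:
            return header + frame.to_csv(index=False)
        with open(path_or_buf, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, index=False)
        return None

    @classmethod
    def from_csv(cls, path_or_buf, cfg: ModelConfig | None = None) -> "PreyField":
        """Read a field written by :meth:`to_csv`."""
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        elif isinstance(path_or_buf, str) and "\n" in path_or_buf:
            text = path_or_buf
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        meta = {}
        for line in text.splitlines():
            if line.startswith("#"):
                for token in line.lstrip("#").split():
                    key, _, value = token.partition("=")
                    meta[key] = float(value)
        frame = pd.read_csv(io.StringIO(text), comment="#")
        cfg = cfg or ModelConfig()
        m_lo = length_to_mass(frame["l_lo"].to_numpy(), cfg)
        m_hi = length_to_mass(frame["l_hi"].to_numpy(), cfg)
        return cls(
            l_center=frame["l_center"].to_numpy(),
            l_lo=frame["l_lo"].to_numpy(),
            l_hi=frame["l_hi"].to_numpy(),
            m=frame["m"].to_numpy(),
            m_lo=m_lo,
            m_hi=m_hi,
            b=frame["b"].to_numpy(),
            c=frame["c"].to_numpy(),
            b_total=meta.get("b_total", float(frame["b"].sum() / MG_M3_TO_UG_MM3)),
            s=meta.get("s", float("nan")),
        )


def length_to_mass(l, cfg: ModelConfig | None = None):
    """Prey dry mass from length via the power law m = a·lᵇ (µg; l in mm).

    The default coefficients (a = 2.5 µg at 1 mm, b = 2.03) represent a fit
    to 0.04–2 mm copepods and protist plankton.
    """
    cfg = cfg or ModelConfig()
    l = np.asarray(l, dtype=float)
    if np.any(l <= 0):
        raise ValidationError("prey length must be strictly positive")
    m = cfg.prey_mass_coeff * l ** cfg.prey_mass_exp
    return float(m) if m.ndim == 0 else m


def build_spectrum(b_total: float, s: float, cfg: ModelConfig | None = None) -> PreyField:
    """Distribute ``b_total`` (mg m⁻³) across the prey bins according to slope ``s``.

    The normalized spectrum assumption — biomass per unit body mass ∝ mˢ —
    gives bin biomass proportional to ∫ mˢ dm over the bin's mass range:
    (m_hiˢ⁺¹ − m_loˢ⁺¹)/(s+1) for s ≠ −1 and ln(m_hi/m_lo) for s = −1.
    Weights are normalized so that Σ b_i equals b_total exactly (after
    conversion to µg mm⁻³); the length–mass coefficient *a* therefore cancels
    from the relative size distribution.
    """
    cfg = cfg or ModelConfig()
    if b_total < 0:
        raise ValidationError("b_total must be non-negative")
    edges = cfg.bin_edges
    l_lo, l_hi = edges[:-1], edges[1:]
    l_center = 0.5 * (l_lo + l_hi)
    m_lo = length_to_mass(l_lo, cfg)
    m_hi = length_to_mass(l_hi, cfg)
    m = length_to_mass(l_center, cfg)

    if s == -1.0:
        weights = np.log(m_hi / m_lo)
    else:
        weights = (m_hi ** (s + 1) - m_lo ** (s + 1)) / (s + 1)
    total_ug = b_total * MG_M3_TO_UG_MM3
    b = total_ug * weights / weights.sum()
    c = np.where(m > 0, b / m, 0.0)
    return PreyField(
        l_center=l_center, l_lo=l_lo, l_hi=l_hi,
        m=m, m_lo=m_lo, m_hi=m_hi, b=b, c=c,
        b_total=float(b_total), s=float(s),
    )


def explicit_field(l_bins, biomasses, cfg: ModelConfig | None = None) -> PreyField:
    """Build a prey field from explicit per-bin biomasses (mg m⁻³ per bin).

    ``l_bins`` are bin-centre lengths in mm; each must match one of the
    configured bins, and every biomass must be non-negative.  Bins not
    listed carry zero biomass.
    """
    cfg = cfg or ModelConfig()
    l_bins = np.asarray(l_bins, dtype=float)
    biomasses = np.asarray(biomasses, dtype=float)
    if l_bins.shape != biomasses.shape:
        raise ValidationError("l_bins and biomasses must have equal length")
    if np.any(biomasses < 0):
        raise ValidationError("biomasses must be non-negative")
    edges = cfg.bin_edges
    centers = cfg.bin_centers
    idx = np.searchsorted(edges, l_bins, side="right") - 1
    if np.any(l_bins < edges[0]) or np.any(l_bins > edges[-1]):
        raise ValidationError(
            f"prey lengths must lie within [{cfg.bin_lo}, {cfg.bin_hi}] mm"
        )
    idx = np.clip(idx, 0, cfg.n_bins - 1)
    b = np.zeros(cfg.n_bins)
    np.add.at(b, idx, biomasses * MG_M3_TO_UG_MM3)
    m_lo = length_to_mass(edges[:-1], cfg)
    m_hi = length_to_mass(edges[1:], cfg)
    m = length_to_mass(centers, cfg)
    return PreyField(
        l_center=centers, l_lo=edges[:-1], l_hi=edges[1:],
        m=m, m_lo=m_lo, m_hi=m_hi, b=b, c=b / m,
        b_total=float(biomasses.sum()), s=float("nan"),
    )
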