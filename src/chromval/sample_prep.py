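"""Sample-preparation bookkeeping: converting between extract concentration
(mg/L), sample content (mg/kg and %w/w) and theoretical fortified content.

The default protocol mirrors the hot-water extraction used for coffee grains:
0.5000 g of homogenised grains extracted into 10 mL, back-extracted into an
equal 10 mL of dichloromethane before injection. The back-extraction is
treated as volume-preserving; any partition loss is absorbed by the recovery
(bias) term of the validation rather than modelled here.

All contents are carried internally as mass fractions; %w/w and mg/kg are
formatting conventions at the interface (1 %w/w == 10000 mg/kg exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import InvalidArgumentError

__all__ = [
    "PrepProtocol",
    "SampleContent",
    "FortifiedContent",
    "extract_to_sample",
    "sample_to_extract",
    "theoretical_fortified_content",
]

MG_PER_KG_PER_PCT = 10000.0  # 1 %w/w expressed in mg/kg


@dataclass(frozen=True)
class PrepProtocol:
    """Masses and volumes of the extraction protocol.

    Parameters
    ----------
    sample_mass_g : float
        Mass of homogenised sample weighed in, grams.
    extraction_volume_ml : float
        Volume of the aqueous extraction, millilitres.
    back_extraction_volume_ml : float
        Volume of the organic back-extraction actually injected from,
        millilitres. This is the volume that scales concentration into
        content.
    dilution_factor : float
        Any additional dilution applied before injection (>= 1).
    """

    sample_mass_g: float = 0.5
    extraction_volume_ml: float = 10.0
    back_extraction_volume_ml: float = 10.0
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sample_mass_g", "extraction_volume_ml",
                     "back_extraction_volume_ml", "dilution_factor"):
            if not getattr(self, name) > 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if self.dilution_factor < 1:
            raise InvalidArgumentError("dilution_factor must be >= 1")

    @property
    def concentration_factor(self) -> float:
        """(mg analyte / kg sample) per (mg analyte / L extract)."""
        volume_l = self.back_extraction_volume_ml / 1000.0
        mass_kg = self.sample_mass_g / 1000.0
        return volume_l / mass_kg * self.dilution_factor


@dataclass(frozen=True)
class SampleContent:
    """Analyte content of a solid sample in both reporting units."""

    mg_per_kg: float
    pct_w_w: float


@dataclass(frozen=True)
class FortifiedContent:
    """Total and spike-only content of a fortified sample, %w/w."""

    total_pct: float
    spike_pct: float


def extract_to_sample(conc_mg_l: float, prep: PrepProtocol) -> SampleContent:
    """Convert an extract concentration into sample content.

    With the default 0.5 g / 10 mL protocol the factor is 20, so an
    instrumental limit of 3.1 mg/L corresponds to 62 mg/kg in the grains.
    """
    if conc_mg_l < 0:
        raise InvalidArgumentError("concentration must be non-negative")
    mg_per_kg = conc_mg_l * prep.concentration_factor
    return SampleContent(mg_per_kg=mg_per_kg, pct_w_w=mg_per_kg / MG_PER_KG_PER_PCT)


def sample_to_extract(pct_w_w: float, prep: PrepProtocol) -> float:
    """Inverse of :func:`extract_to_sample`: %w/w content -> extract mg/L."""
    if pct_w_w < 0:
        raise InvalidArgumentError("content must be non-negative")
    return pct_w_w * MG_PER_KG_PER_PCT / prep.concentration_factor


def theoretical_fortified_content(background_pct: float, spike_pct: float) -> FortifiedContent:
    """Total content of a fortified sample: background + spike, %w/w.

    The spike is returned alongside because recovery is computed against the
    spike alone while Horwitz-type precision criteria conventionally use the
    total content.
    """
    if background_pct < 0 or spike_pct < 0:
        raise InvalidArgumentError("contents must be non-negative")
    return FortifiedContent(total_pct=background_pct + spike_pct, spike_pct=spike_pct)
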