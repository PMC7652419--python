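"""Compartmental glucose-oxidation rates from ¹³C-NMR isotopomer data.

After a timed [1,6-¹³C₂]glucose infusion, ¹³C label is trapped in the amino
acid pools of glutamatergic and GABAergic neurons (Glu, Gln, Asp via the
neuronal TCA cycle; GABA via glutamate decarboxylation).  Position-specific
percentage enrichments (Glu_C4, Glu_C3, GABA_C2, GABA_C4, Asp_C3, Gln_C4),
pool concentrations measured against a [2-¹³C]glycine internal standard, and
the plasma glucose-C1 enrichment together determine the metabolic rates of
glucose oxidation in glutamatergic neurons (MR_Glu), GABAergic neurons
(MR_GABA), and all neurons (MR_Total) through fixed linear combinations:

    MR_Glu   = 0.5 · (1/10) · (1/Glc_C1) · {0.82·[Glu]·(Glu_C4 + 2·Glu_C3)
                                            + 0.42·[Asp]·(2·Asp_C3)}
    MR_GABA  = 0.5 · (1/10) · (1/Glc_C1) · {0.02·[Glu]·(Glu_C4 + 2·Glu_C3)
                                            + [GABA]·(GABA_C2 + 2·GABA_C4)
                                            + 0.42·[Asp]·(2·Asp_C3)}
    MR_Total = 0.5 · (1/10) · (1/Glc_C1) · {[Glu]·(Glu_C4 + 2·Glu_C3)
                                            + [GABA]·(GABA_C2 + 2·GABA_C4)
                                            + [Asp]·(2·Asp_C3)
                                            + [Gln]·Gln_C4}

Enrichments and Glc_C1 enter in percent; concentrations in µmol/g wet
weight.  Rates are reported as µmol·g⁻¹·min⁻¹ (as-printed formula; the
dimensional role of the 1/10 factor is not derivable from its source and is
carried verbatim).  Note the aspartate term of MR_Total carries no 0.42
coefficient, which is what guarantees MR_Total ≥ MR_Glu + MR_GABA on
nonnegative inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "FLUX_CONSTANTS",
    "FluxModelConstants",
    "IsotopomerSample",
    "FluxResult",
    "enrichment_from_areas",
    "correct_natural_abundance",
    "conc_from_reference",
    "mr_glu",
    "mr_gaba",
    "mr_total",
    "compute_fluxes",
    "samples_from_table",
    "fluxes_to_frame",
]

#: Percent ¹³C natural abundance subtracted from tissue enrichments.
NATURAL_ABUNDANCE_PCT = 1.1

# Enrichment positions required by the rate formulas.
ENRICH_POSITIONS = ("glu_c4", "glu_c3", "gaba_c2", "gaba_c4", "asp_c3", "gln_c4")
CONC_METABOLITES = ("glu", "gaba", "asp", "gln")


@dataclass(frozen=True)
class FluxModelConstants:
    """Fixed coefficients of the three rate formulas (dimensionless)."""

    prefactor: float = 0.5
    scale: float = 0.1  # the printed 1/10
    glu_coeff_in_glu: float = 0.82
    asp_coeff: float = 0.42
    glu_coeff_in_gaba: float = 0.02


FLUX_CONSTANTS = FluxModelConstants()


@dataclass
class IsotopomerSample:
    """Per-sample pool concentrations and position-specific enrichments.

    Parameters
    ----------
    conc
        Metabolite concentrations in µmol/g; keys must include
        ``glu, gaba, asp, gln`` (lower case).
    enrich
        Percent ¹³C excess per labelled position; keys from
        ``ENRICH_POSITIONS``.
    glc_c1
        Percent plasma glucose-C1 enrichment; must be > 0 for flux
        computation.
    tissue, subject
        Provenance labels.
    """

    conc: Mapping[str, float]
    enrich: Mapping[str, float]
    glc_c1: float
    tissue: str = "hippocampus"
    subject: str = ""

    def __post_init__(self) -> None:
        for pos, val in self.enrich.items():
            if not (0.0 <= val <= 100.0):
                raise ValueError(f"enrichment {pos}={val} outside [0, 100] percent")
        for met, val in self.conc.items():
            if val < 0:
                raise ValueError(f"negative concentration for {met}: {val}")
        vals = [v for v in self.enrich.values()]
        if vals and any(v > 0 for v in vals) and all(v < 1.0 for v in vals):
            warnings.warn(
                "all enrichments are below 1: inputs look fraction-scaled, "
                "but the rate formulas expect percent",
                UserWarning,
                stacklevel=2,
            )

    def _require(self, concs: tuple[str, ...], positions: tuple[str, ...]) -> None:
        missing = [m for m in concs if m not in self.conc]
        missing += [p for p in positions if p not in self.enrich]
        if missing:
            raise KeyError(f"sample is missing required entries: {missing}")
        if self.glc_c1 <= 0:
            raise ValueError("glc_c1 must be > 0 to compute fluxes")


@dataclass
class FluxResult:
    """The three glucose-oxidation rates for one sample (µmol·g⁻¹·min⁻¹)."""

    mr_glu: float
    mr_gaba: float
    mr_total: float
    subject: str = ""
    tissue: str = ""


def enrichment_from_areas(area_13c: float, area_total: float) -> float:
    """Percent enrichment from a ¹³C-coupled peak area and the total area.

    For plasma glucose the ¹³C area is the summed satellite area and the
    total is the full ¹H resonance (¹²C + ¹³C); for tissue metabolites the
    ¹³C area comes from the edited difference spectrum and the total from
    the non-edited spectrum.
    """
    if area_total <= 0:
        raise ValueError("area_total must be > 0")
    if area_13c < 0 or area_13c > area_total:
        raise ValueError(
            "area_13c must lie in [0, area_total]; a larger value signals a "
            "peak-integration error"
        )
    return 100.0 * area_13c / area_total


def correct_natural_abundance(enrichment: float) -> float:
    """Subtract the 1.1% ¹³C natural abundance, flooring at zero."""
    if enrichment < 0:
        raise ValueError("enrichment must be >= 0")
    return max(enrichment - NATURAL_ABUNDANCE_PCT, 0.0)


def conc_from_reference(
    area_met: float,
    area_gly: float,
    gly_amount: float = 0.2,
    tissue_mass: float = 0.03,
    proton_ratio: float = 1.0,
) -> float:
    """Concentration (µmol/g) of a metabolite against the glycine standard.

    ``gly_amount`` is the µmol of [2-¹³C]glycine added to the extract
    (0.2 µmol by default), ``tissue_mass`` the wet weight in g, and
    ``proton_ratio`` the metabolite's proton count at the integrated
    resonance relative to glycine's — the per-proton normalisation is not
    part of the printed procedure, so it defaults to 1 and is exposed
    explicitly.
    """
    if area_met < 0:
        raise ValueError("area_met must be >= 0")
    if area_gly <= 0 or tissue_mass <= 0 or proton_ratio <= 0:
        raise ValueError("area_gly, tissue_mass and proton_ratio must be > 0")
    return (area_met / area_gly) * (gly_amount / tissue_mass) / proton_ratio


def _prefactor(s: IsotopomerSample, c: FluxModelConstants) -> float:
    return c.prefactor * c.scale / s.glc_c1


def mr_glu(s: IsotopomerSample, constants: FluxModelConstants = FLUX_CONSTANTS) -> float:
    """Glucose-oxidation rate of glutamatergic neurons (µmol·g⁻¹·min⁻¹)."""
    s._require(("glu", "asp"), ("glu_c4", "glu_c3", "asp_c3"))
    c, e = s.conc, s.enrich
    return _prefactor(s, constants) * (
        constants.glu_coeff_in_glu * c["glu"] * (e["glu_c4"] + 2.0 * e["glu_c3"])
        + constants.asp_coeff * c["asp"] * (2.0 * e["asp_c3"])
    )


def mr_gaba(s: IsotopomerSample, constants: FluxModelConstants = FLUX_CONSTANTS) -> float:
    """Glucose-oxidation rate of GABAergic neurons (µmol·g⁻¹·min⁻¹)."""
    s._require(
        ("glu", "gaba", "asp"),
        ("glu_c4", "glu_c3", "gaba_c2", "gaba_c4", "asp_c3"),
    )
    c, e = s.conc, s.enrich
    return _prefactor(s, constants) * (
        constants.glu_coeff_in_gaba * c["glu"] * (e["glu_c4"] + 2.0 * e["glu_c3"])
        + c["gaba"] * (e["gaba_c2"] + 2.0 * e["gaba_c4"])
        + constants.asp_coeff * c["asp"] * (2.0 * e["asp_c3"])
    )


def mr_total(s: IsotopomerSample, constants: FluxModelConstants = FLUX_CONSTANTS) -> float:
    """Total neuronal glucose-oxidation rate (µmol·g⁻¹·min⁻¹).

    The glutamine term is [Gln]·Gln_C4; the aspartate term carries no 0.42
    coefficient, unlike MR_Glu and MR_GABA.
    """
    s._require(CONC_METABOLITES, ENRICH_POSITIONS)
    c, e = s.conc, s.enrich
    return _prefactor(s, constants) * (
        c["glu"] * (e["glu_c4"] + 2.0 * e["glu_c3"])
        + c["gaba"] * (e["gaba_c2"] + 2.0 * e["gaba_c4"])
        + c["asp"] * (2.0 * e["asp_c3"])
        + c["gln"] * e["gln_c4"]
    )


def compute_fluxes(s: IsotopomerSample) -> FluxResult:
    """All three rates for one sample."""
    return FluxResult(
        mr_glu=mr_glu(s),
        mr_gaba=mr_gaba(s),
        mr_total=mr_total(s),
        subject=s.subject,
        tissue=s.tissue,
    )


def samples_from_table(
    table: pd.DataFrame, correct_na: bool = True
) -> list[IsotopomerSample]:
    """Build samples from a long-format table.

    Expected columns: ``subject, tissue, name, value, kind`` with
    ``kind`` ∈ {conc, enrich, glc_c1}.  ``name`` is a metabolite for conc
    rows and a labelled position for enrich rows.  When ``correct_na`` is
    true the 1.1% natural abundance is subtracted from every tissue
    enrichment (never from plasma glc_c1, whose satellite-based measurement
    already isolates the ¹³C-coupled signal).
    """
    required = {"subject", "tissue", "name", "value", "kind"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    samples = []
    for (subject, tissue), grp in table.groupby(["subject", "tissue"], sort=True):
        conc = {
            r["name"].lower(): float(r["value"])
            for _, r in grp[grp["kind"] == "conc"].iterrows()
        }
        enrich = {
            r["name"].lower(): float(r["value"])
            for _, r in grp[grp["kind"] == "enrich"].iterrows()
        }
        if correct_na:
            enrich = {k: correct_natural_abundance(v) for k, v in enrich.items()}
        glc_rows = grp[grp["kind"] == "glc_c1"]
        if len(glc_rows) != 1:
            raise ValueError(f"sample {subject}/{tissue} needs exactly one glc_c1 row")
        samples.append(
            IsotopomerSample(
                conc=conc,
                enrich=enrich,
                glc_c1=float(glc_rows["value"].iloc[0]),
                tissue=str(tissue),
                subject=str(subject),
            )
        )
    return samples


def fluxes_to_frame(results: list[FluxResult]) -> pd.DataFrame:
    """Tidy per-sample flux table (subject, tissue, mr_glu, mr_gaba, mr_total)."""
    return pd.DataFrame(
        [
            {
                "subject": r.subject,
                "tissue": r.tissue,
                "mr_glu": r.mr_glu,
                "mr_gaba": r.mr_gaba,
                "mr_total": r.mr_total,
            }
            for r in results
        ]
    )
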