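"""Packaged study tables for the vanillic-acid pharmacosome optimization.

The 13-run central composite design with its measured particle size (PS,
nm), polydispersity index (PDI) and zeta potential (ZP, mV) ships as a CSV
data file; the remaining printed tables (optimum validation, solubilities,
HPLC calibration statistics, group-level non-compartmental parameters) are
small enough to live as constants here.

Two documented corrections are applied to the design table: run F5's actual
PC:VA level is a misprint (1.050 for the center level 2.050; the coded
levels are the ground truth and the actual columns are derived from them),
and zeta potential is stored as printed (negative mV) but flagged for
magnitude analysis, because its response model intercept matches the
center-point |ZP| mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .design import FactorSpec, ResponseTable, read_response_table

__all__ = ["PaperFixtures", "fixtures", "TABLE1_FACTORS"]

TABLE1_FACTORS = (
    FactorSpec(name="PC:VA molar ratio", center=2.050, half_range=0.750, units=""),
    FactorSpec(
        name="precursor concentration", center=50.000, half_range=25.000, units="mg/mL"
    ),
)

# optimum suggested by the desirability run, and the prepared formulation
TABLE3 = {
    "optimum_actual": {"PC:VA molar ratio": 1.3, "precursor concentration": 53.164},
    "expected": {"PS": 278.928, "PDI": 0.312, "ZP": -25.0},
    "observed": {"PS": 229.7, "PDI": 0.29, "ZP": -30.8},
    "observed_sd": {"PS": 3.76, "PDI": 0.07, "ZP": 1.87},
    "percent_bias_printed": {"PS": 21.43, "PDI": 7.05, "ZP": 23.20},
    "desirability": 0.522,
}

# saturated solubilities (µg/mL) and partition behaviour
TABLE4 = {
    "VA": {"water": 543.9, "octanol": 1948.8, "P": 3.58, "logP": 0.553},
    "pharmacosomes": {"water": 1053.5, "octanol": 29880.0, "P": 28.36, "logP": 1.45},
}

# HPLC-UV validation sheet
TABLE5 = {
    "linearity_ug_ml": (1.0, 200.0),
    "r": 0.9999,
    "slope": 2.291,
    "intercept": 0.7938,
    "sd_residuals": 0.2201,
    "lod_ug_ml": 0.317,
    "loq_ug_ml": 0.961,
    "tailing_factor": 1.04,
    "capacity_factor": 2.11,
    "plate_number": 5884,
    "hetp": 0.06,
    "resolution": 2.08,
}

# group-level non-compartmental parameters (mean values); dose 10 mg/kg oral.
# The AUC0-24 column of the formulation group is internally inconsistent in
# the source table and is excluded.
TABLE6 = {
    "dose_mg_kg": 10.0,
    "schedule_min": (10.0, 20.0, 30.0, 60.0, 90.0, 120.0, 360.0, 1440.0, 2880.0),
    "standard": {
        "cmax": 132.65,
        "tmax": 10.0,
        "auc_inf": 72517.20,
        "aumc_last": 31061100.0,
        "aumc_inf": 41480100.0,
        "mrt": 572.0,
    },
    "pharmacosomes": {
        "cmax": 173.72,
        "tmax": 30.0,
        "auc_inf": 278594.41,
        "aumc_last": 250889000.0,
        "aumc_inf": 486900000.0,
        "mrt": 1747.71,
    },
    "relative_bioavailability_pct": 384.0,
}


@dataclass(frozen=True)
class PaperFixtures:
    table1: ResponseTable
    table3: dict
    table4: dict
    table5: dict
    table6: dict

    @property
    def design(self):
        return self.table1.design


def fixtures() -> PaperFixtures:
    """Load the packaged study tables (design responses from the data CSV)."""
    path = resources.files("pharmrsm").joinpath("data/table1.csv")
    with resources.as_file(path) as p:
        table1 = read_response_table(
            p, factors=TABLE1_FACTORS, magnitude_responses={"ZP"}
        )
    return PaperFixtures(
        table1=table1, table3=TABLE3, table4=TABLE4, table5=TABLE5, table6=TABLE6
    )
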