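"""Reference parameterization of the rat S-1 study this package models.

These constants are the published population estimates and noncompartmental
summary statistics of the two-arm rat experiment (5 rats per arm, oral S-1 at
5 mg/kg tegafur / 1.45 mg/kg gimeracil, after seven days of pretreatment with
either vehicle or the herbal decoction Sipjeondaebo-tang, "SDT").  They are
the defaults of the synthetic-study generator and the inputs of the
reproduction pipeline; nothing in the estimation code reads them.
"""

from __future__ import annotations

from .model import StructuralParams

__all__ = [
    "CONTROL_PARAMS",
    "PRETREATED_PARAMS",
    "GROUP_RATIOS",
    "BSV_OMEGA2",
    "TEGAFUR_DOSE",
    "GIMERACIL_DOSE",
    "IV_5FU_DOSE",
    "SAMPLING_TIMES",
    "IV_SAMPLING_TIMES",
    "LLOQ",
    "NCA_SUMMARY",
    "IV_5FU_HALF_LIFE_MIN",
]

#: oral dose of tegafur within S-1 (mg/kg)
TEGAFUR_DOSE = 5.0
#: oral dose of gimeracil within S-1 (mg/kg)
GIMERACIL_DOSE = 1.45
#: intravenous 5-FU dose of the auxiliary disposition arm (mg/kg)
IV_5FU_DOSE = 10.0

#: nominal post-dose sampling schedule (h); predose is handled separately
SAMPLING_TIMES = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 8.0, 12.0, 24.0)

#: dense early schedule (h) for the IV 5-FU arm (terminal half-life ~15-20 min)
IV_SAMPLING_TIMES = (0.033, 0.083, 0.167, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0)

#: lower limits of quantification (ng/mL) per analyte
LLOQ = {"tegafur": 50.0, "5fu": 10.0, "gimeracil": 50.0}

#: population typical values, control (vehicle-pretreated) group
CONTROL_PARAMS = StructuralParams(
    ka=0.296,
    ka_met=0.122,
    k_conv=2.88,
    cl_teg=0.0813,
    cld_teg=0.184,
    f_met=0.342,
    cl_5fu=3.52,
    cld_5fu=1.87,
    v1_teg=0.0464,
    v2_teg=0.137,
    v1_5fu=0.623,
    v2_5fu=0.294,
)

#: population typical values, herb-pretreated group (shared disposition except
#: the separately estimated ka, ka_met and cl_5fu)
PRETREATED_PARAMS = CONTROL_PARAMS.replace(ka=0.197, ka_met=0.0595, cl_5fu=5.93)

#: multiplicative pretreatment effects (pretreated / control typical values)
GROUP_RATIOS = {
    "ka": PRETREATED_PARAMS.ka / CONTROL_PARAMS.ka,
    "ka_met": PRETREATED_PARAMS.ka_met / CONTROL_PARAMS.ka_met,
    "cl_5fu": PRETREATED_PARAMS.cl_5fu / CONTROL_PARAMS.cl_5fu,
}

#: between-subject variability, interpreted as variances of log-parameters
#: (the reporting convention of the estimation software used in the source
#: study; a SD interpretation is available via PopulationModel.bsv_is_sd)
BSV_OMEGA2 = {
    "ka": 0.0101,
    "ka_met": 0.308,
    "k_conv": 0.747,
    "cl_teg": 0.00221,
    "f_met": 0.0162,
    "cl_5fu": 0.163,
    "cld_teg": 0.105,
    "cld_5fu": 0.168,
    "v1_teg": 0.729,
    "v2_teg": 0.0141,
    "v1_5fu": 0.291,
    "v2_5fu": 0.184,
}

#: published IV 5-FU terminal half-life, minutes (mean, SD)
IV_5FU_HALF_LIFE_MIN = (19.3, 7.5)

#: noncompartmental summary of the multiple-dose pretreatment experiment:
#: analyte -> parameter -> group -> (mean, SD), n = 5 rats per group.
#: Units: t_half h, tmax h, cmax ng/mL, AUCs ng.h/mL, cl_f mL/min/kg,
#: vz_f L/kg, auc_ratio %.
NCA_SUMMARY = {
    "tegafur": {
        "t_half": {"control": (2.2, 1.4), "pretreated": (3.3, 0.8)},
        "tmax": {"control": (1.2, 0.7), "pretreated": (3.2, 1.6)},
        "cmax": {"control": (6828.0, 384.0), "pretreated": (4960.0, 431.9)},
        "auc_all": {"control": (43496.9, 4673.0), "pretreated": (46842.4, 8127.5)},
        "auc_inf": {"control": (43748.1, 4835.6), "pretreated": (47461.3, 8163.9)},
        "cl_f": {"control": (1.9, 0.2), "pretreated": (1.8, 0.3)},
        "vz_f": {"control": (0.4, 0.2), "pretreated": (0.5, 0.1)},
    },
    "5fu": {
        "t_half": {"control": (3.0, 0.9), "pretreated": (3.1, 0.8)},
        "tmax": {"control": (1.8, 0.3), "pretreated": (2.4, 0.5)},
        "cmax": {"control": (172.2, 40.4), "pretreated": (64.3, 23.0)},
        "auc_all": {"control": (639.3, 190.0), "pretreated": (362.7, 96.2)},
        "auc_inf": {"control": (750.2, 145.8), "pretreated": (429.6, 83.2)},
        "auc_ratio": {"control": (2.7, 0.7), "pretreated": (1.5, 0.5)},
    },
    "gimeracil": {
        "t_half": {"control": (0.7, 0.1), "pretreated": (0.8, 0.2)},
        "tmax": {"control": (0.5, 0.0), "pretreated": (0.7, 0.5)},
        "cmax": {"control": (347.8, 42.7), "pretreated": (142.3, 41.8)},
        "auc_all": {"control": (449.5, 74.2), "pretreated": (180.2, 41.5)},
        "auc_inf": {"control": (526.6, 85.4), "pretreated": (247.4, 57.4)},
        "cl_f": {"control": (46.9, 7.8), "pretreated": (101.9, 22.6)},
        "vz_f": {"control": (2.8, 0.4), "pretreated": (6.8, 0.9)},
    },
}
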