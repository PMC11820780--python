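"""Built-in assay descriptions and reference tables.

Everything here is plain data a user could equally supply from files: the two
LC gradient programs of the published dual-method assay, the NIST SRM 1950
trueness worked example (certified and measured plasma concentrations), a
~20-analyte fixture registry for examples and tests, and a builder for a
full-scale registry with the published assay's structure (235 analytes, two
transitions each except three single-transition compounds, six analytes
acquired in both polarities).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .registry import (
    AnalyteDefinition,
    GradientProgram,
    Method,
    Polarity,
    Registry,
    TransitionRecord,
    TransitionRole,
)

__all__ = [
    "rp_gradient",
    "hilic_gradient",
    "nist_srm1950_table",
    "fixture_registry",
    "build_full_scale_registry",
]


def rp_gradient() -> GradientProgram:
    """Reversed-phase gradient: 5% B hold, ramp to 100% B, high-flow wash,
    re-equilibration at 5% B ending at 23.0 min."""
    return GradientProgram(
        method=Method.RP,
        segments=[
            (0.0, 5.0, 400.0),
            (0.5, 5.0, 400.0),
            (8.0, 100.0, 400.0),
            (9.5, 100.0, 800.0),
            (19.5, 100.0, 800.0),
            (23.0, 5.0, 400.0),
        ],
        oven_temp_C=50.0,
        injection_volume_uL=1.0,
    )


def hilic_gradient() -> GradientProgram:
    """HILIC gradient (percent B = aqueous phase): gradient to the 40% ACN
    isocratic wash, then re-equilibration at 100% A ending at 16.5 min."""
    return GradientProgram(
        method=Method.HILIC,
        segments=[
            (0.0, 0.0, 400.0),
            (0.5, 0.0, 400.0),
            (6.5, 36.8, 400.0),
            (6.8, 57.9, 400.0),
            (12.0, 57.9, 400.0),
            (12.8, 0.0, 400.0),
            (13.3, 0.0, 1000.0),
            (15.8, 0.0, 1000.0),
            (16.5, 0.0, 400.0),
        ],
        oven_temp_C=40.0,
        injection_volume_uL=1.0,
    )


def nist_srm1950_table() -> pd.DataFrame:
    """Certified and measured concentrations (µg/L) in NIST SRM 1950 plasma.

    Cholecalciferol and calciferol were below the method's detection limits
    (``measured_ugL`` is NaN); they are not evaluable for trueness.
    """
    rows = [
        ("Methionine", 3325.0, 2146.0),
        ("Leucine", 13158.0, 9038.0),
        ("Proline", 20298.0, 15859.0),
        ("Valine", 21318.0, 17053.0),
        ("Threonine", 14219.0, 11915.0),
        ("Alanine", 26724.0, 22449.0),
        ("Serine", 10067.0, 9218.0),
        ("Isoleucine", 7273.0, 6823.0),
        ("Tyrosine", 10373.0, 9770.0),
        ("Phenylalanine", 8364.0, 8287.0),
        ("Lysine", 20400.0, 23637.0),
        ("Arginine", 14168.0, 23863.0),
        ("Creatinine", 6789.0, 7672.0),
        ("Urea", 234500.0, 224888.0),
        ("Cholesterol", 1514000.0, 645655.0),
        ("Cholecalciferol", 25.0, np.nan),
        ("Calciferol", 1.0, np.nan),
    ]
    return pd.DataFrame(rows, columns=["analyte", "certified_ugL", "measured_ugL"])


# ---------------------------------------------------------------------------
# fixture registry (~20 analytes) used in examples and tests

_FIXTURE_ROWS = [
    # analyte_id, name, class, method, polarity, prec, prod, role, rt, win, calib_set, flags
    ("leu_ile_sum", "Leucine+Isoleucine (sum)", "amino acids", "HILIC", "positive", 132.1, 86.1, "quantifier", 5.05, 30, "HILIC", "report_as_sum;unique_partner=ile"),
    ("leu_ile_sum", "Leucine+Isoleucine (sum)", "amino acids", "HILIC", "positive", 132.1, 89.0, "qualifier", 5.05, 30, "HILIC", "report_as_sum;unique_partner=ile"),
    ("ile", "Isoleucine", "amino acids", "HILIC", "positive", 132.1, 69.0, "quantifier", 5.05, 30, "HILIC", "sum_partner=leu_ile_sum"),
    ("ile", "Isoleucine", "amino acids", "HILIC", "positive", 132.1, 86.1, "qualifier", 5.05, 30, "HILIC", "sum_partner=leu_ile_sum"),
    ("val", "Valine", "amino acids", "HILIC", "positive", 118.1, 72.1, "quantifier", 5.30, 30, "HILIC", ""),
    ("val", "Valine", "amino acids", "HILIC", "positive", 118.1, 55.1, "qualifier", 5.30, 30, "HILIC", ""),
    ("met", "Methionine", "amino acids", "HILIC", "positive", 150.1, 104.0, "quantifier", 5.15, 30, "HILIC", ""),
    ("met", "Methionine", "amino acids", "HILIC", "positive", 150.1, 56.1, "qualifier", 5.15, 30, "HILIC", ""),
    ("ser", "Serine", "amino acids", "HILIC", "positive", 106.0, 60.0, "quantifier", 6.10, 30, "HILIC", "both_polarities"),
    ("ser", "Serine", "amino acids", "HILIC", "negative", 104.0, 74.0, "qualifier", 6.10, 30, "HILIC", "both_polarities"),
    ("thr", "Threonine", "amino acids", "HILIC", "positive", 120.1, 74.1, "quantifier", 5.80, 30, "HILIC", ""),
    ("thr", "Threonine", "amino acids", "HILIC", "positive", 120.1, 56.1, "qualifier", 5.80, 30, "HILIC", ""),
    ("ala", "Alanine (sum isobars)", "amino acids", "HILIC", "positive", 90.1, 44.1, "quantifier", 6.00, 30, "HILIC", "report_as_sum"),
    ("ala", "Alanine (sum isobars)", "amino acids", "HILIC", "positive", 90.1, 72.0, "qualifier", 6.00, 30, "HILIC", "report_as_sum"),
    ("crea", "Creatinine", "biogenic amines", "HILIC", "positive", 114.1, 44.2, "quantifier", 4.30, 30, "HILIC", ""),
    ("crea", "Creatinine", "biogenic amines", "HILIC", "positive", 114.1, 86.0, "qualifier", 4.30, 30, "HILIC", ""),
    ("urea", "Urea", "biogenic amines", "HILIC", "positive", 61.0, 44.0, "quantifier", 3.10, 30, "HILIC", ""),
    ("urea", "Urea", "biogenic amines", "HILIC", "positive", 61.0, 43.0, "qualifier", 3.10, 30, "HILIC", ""),
    ("tmao", "Trimethylamine-N-oxide", "biogenic amines", "HILIC", "positive", 76.1, 58.1, "quantifier", 5.95, 30, "HILIC", ""),
    ("tmao", "Trimethylamine-N-oxide", "biogenic amines", "HILIC", "positive", 76.1, 59.1, "qualifier", 5.95, 30, "HILIC", ""),
    ("glc", "Glucose (sum hexoses)", "sugars", "HILIC", "negative", 179.1, 89.0, "quantifier", 6.80, 30, "HILIC", "report_as_sum"),
    ("glc", "Glucose (sum hexoses)", "sugars", "HILIC", "negative", 179.1, 59.0, "qualifier", 6.80, 30, "HILIC", "report_as_sum"),
    ("hip", "Hippuric acid", "carboxylic acids", "RP", "negative", 178.1, 134.1, "quantifier", 2.90, 30, "RP_Aqu", ""),
    ("hip", "Hippuric acid", "carboxylic acids", "RP", "negative", 178.1, 77.0, "qualifier", 2.90, 30, "RP_Aqu", ""),
    ("ips", "3-Indoxylsulfate", "carboxylic acids", "RP", "negative", 212.0, 132.0, "quantifier", 2.60, 30, "RP_Aqu", ""),
    ("ips", "3-Indoxylsulfate", "carboxylic acids", "RP", "negative", 212.0, 80.0, "qualifier", 2.60, 30, "RP_Aqu", ""),
    ("gca", "Glycocholic acid", "bile acids", "RP", "negative", 464.3, 74.0, "quantifier", 5.40, 30, "RP_Aqu", "both_polarities"),
    ("gca", "Glycocholic acid", "bile acids", "RP", "positive", 466.3, 337.3, "qualifier", 5.40, 30, "RP_Aqu", "both_polarities"),
    ("cdca", "Chenodeoxycholic acid", "bile acids", "RP", "negative", 391.3, 391.3, "quantifier", 7.20, 30, "RP_Aqu", ""),
    ("cdca", "Chenodeoxycholic acid", "bile acids", "RP", "negative", 391.3, 373.3, "qualifier", 7.20, 30, "RP_Aqu", ""),
    ("ola", "Oleic acid", "fatty acids", "RP", "negative", 281.2, 281.2, "quantifier", 9.80, 30, "RP_Hep", ""),
    ("ola", "Oleic acid", "fatty acids", "RP", "negative", 281.2, 263.2, "qualifier", 9.80, 30, "RP_Hep", ""),
    ("lna", "Linoleic acid", "fatty acids", "RP", "negative", 279.2, 279.2, "quantifier", 9.50, 30, "RP_Hep", ""),
    ("lna", "Linoleic acid", "fatty acids", "RP", "negative", 279.2, 261.2, "qualifier", 9.50, 30, "RP_Hep", ""),
    ("chol", "Cholesterol", "sterols", "RP", "positive", 369.3, 161.1, "quantifier", 10.80, 30, "RP_Hep", ""),
    ("chol", "Cholesterol", "sterols", "RP", "positive", 369.3, 147.1, "qualifier", 10.80, 30, "RP_Hep", ""),
    ("pc_26", "1-stearoyl-2-arachidonoyl-PC", "phospholipids", "RP", "positive", 810.6, 184.1, "quantifier", 12.40, 60, "RP_Hep", ""),
    ("pc_26", "1-stearoyl-2-arachidonoyl-PC", "phospholipids", "RP", "positive", 810.6, 86.1, "qualifier", 12.40, 60, "RP_Hep", ""),
    ("sm_16", "C16 sphingomyelin", "phospholipids", "RP", "positive", 703.6, 184.1, "quantifier", 12.10, 60, "RP_Hep", ""),
    ("sm_16", "C16 sphingomyelin", "phospholipids", "RP", "positive", 703.6, 86.1, "qualifier", 12.10, 60, "RP_Hep", ""),
    ("chol_myr", "Cholesteryl myristate", "cholesterol esters", "RP", "positive", 614.6, 369.3, "quantifier", 14.20, 30, "RP_Hep", "single_transition"),
    ("hpaa", "3-Hydroxyphenylacetic acid", "carboxylic acids", "RP", "negative", 151.0, 107.0, "quantifier", 2.30, 30, "RP_Aqu", "single_transition"),
]


def fixture_registry() -> Registry:
    """A small (~20 analyte) registry spanning both LC methods, both
    polarities, single-transition compounds, wide-window phospholipids and
    the leucine/isoleucine deconvolution pair."""
    analytes: dict[str, AnalyteDefinition] = {}
    transitions: list[TransitionRecord] = []
    for (aid, name, cls, method, pol, prec, prod, role, rt, win, cset, flags) in _FIXTURE_ROWS:
        if aid not in analytes:
            flag_map = {
                k.split("=")[0]: (k.split("=")[1] if "=" in k else True)
                for k in flags.split(";")
                if k
            }
            analytes[aid] = AnalyteDefinition(
                analyte_id=aid,
                name=name,
                compound_class=cls,
                calibration_set=cset,
                single_transition=bool(flag_map.get("single_transition", False)),
                both_polarities=bool(flag_map.get("both_polarities", False)),
                report_as_sum=bool(flag_map.get("report_as_sum", False)),
                sum_partner=flag_map.get("sum_partner"),
                unique_partner=flag_map.get("unique_partner"),
            )
        transitions.append(
            TransitionRecord(
                analyte_id=aid,
                method=Method(method),
                polarity=Polarity(pol),
                precursor_mz=prec,
                product_mz=prod,
                role=TransitionRole(role),
                retention_time=rt,
                window_width=float(win),
            )
        )
    return Registry(analytes=list(analytes.values()), transitions=transitions)


def build_full_scale_registry(
    n_analytes: int = 235,
    n_single_transition: int = 3,
    n_both_polarities: int = 6,
    seed: int = 0,
) -> Registry:
    """Synthesize a registry with the full assay's structure.

    The published assay registers 235 analytes with two SRM transitions each,
    except three compounds with only one reliable transition, giving
    235 x 2 - 3 = 467 transitions; six analytes (serine, myo-inositol, four
    bile acids) spread their two transitions across both polarities.  This
    builder reproduces that structure with synthetic m/z and retention times
    (clustered elution like the real assay, HILIC mostly 1-8 min, RP 2-15
    min), for scheduler and registry-scale work without the proprietary
    appendix table.
    """
    rng = np.random.default_rng(seed)
    analytes: list[AnalyteDefinition] = []
    transitions: list[TransitionRecord] = []
    n_hilic = n_analytes // 2
    for i in range(n_analytes):
        aid = f"syn{i:03d}"
        method = Method.HILIC if i < n_hilic else Method.RP
        single = i < n_single_transition
        both_pol = (not single) and (n_single_transition <= i < n_single_transition + n_both_polarities)
        if method == Method.HILIC:
            # bimodal elution: clusters near 5 and 8 min
            rt = float(
                rng.normal(5.0, 0.8) if rng.random() < 0.6 else rng.normal(8.0, 1.0)
            )
            rt = min(max(rt, 0.8), 12.0)
        else:
            rt = float(min(max(rng.normal(9.0, 3.0), 2.0), 15.0))
        pol = Polarity.positive if rng.random() < 0.7 else Polarity.negative
        prec = float(rng.uniform(70, 900))
        analytes.append(
            AnalyteDefinition(
                analyte_id=aid,
                name=aid,
                compound_class="synthetic",
                calibration_set="HILIC" if method == Method.HILIC else "RP_Aqu",
                single_transition=single,
                both_polarities=both_pol,
            )
        )
        roles = (
            [TransitionRole.quantifier]
            if single
            else [TransitionRole.quantifier, TransitionRole.qualifier]
        )
        for j, role in enumerate(roles):
            t_pol = pol
            if both_pol and j == 1:
                t_pol = (
                    Polarity.negative if pol == Polarity.positive else Polarity.positive
                )
            transitions.append(
                TransitionRecord(
                    analyte_id=aid,
                    method=method,
                    polarity=t_pol,
                    precursor_mz=prec,
                    product_mz=float(rng.uniform(40, prec)),
                    role=role,
                    retention_time=rt,
                    window_width=30.0,
                )
            )
    return Registry(analytes=analytes, transitions=transitions)
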