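"""Reference parameter sets for POPC/POPG-cholesterol membranes with [C12MIM]+Br-.

These are the published assay readouts for cholesterol-containing POPC
(PC) and POPG (PG) vesicle and monolayer systems exposed to the
imidazolium ionic liquid 1-dodecyl-3-methylimidazolium bromide.  The
package uses them as generator ground truth for round-trip recovery
(the ``reproduce`` workflow and the acceptance checks): simulate an
assay with these parameters, run the analysis, and compare.

``None`` marks a rate or half-time that was too fast or too slow to
yield a meaningful fit ('N.D.').
"""

#: Leakage kinetics: system -> dict(k [1/min], a0 [%], tc [min]).
LEAKAGE_KINETICS = {
    "PC/Chol (10:0)": {"k": 0.52, "a0": 99.1, "tc": 0.87},
    "PC/Chol (9:1)": {"k": 0.55, "a0": 98.6, "tc": 0.41},
    "PC/Chol (8:2)": {"k": 0.17, "a0": 40.7, "tc": 11.47},
    "PC/Chol (7:3)": {"k": 0.18, "a0": 57.3, "tc": 4.94},
    "PC/Chol (6:4)": {"k": 0.17, "a0": 62.0, "tc": 0.98},
    "PG/Chol (10:0)": {"k": 0.15, "a0": 24.60, "tc": 16.21},
    "PG/Chol (9:1)": {"k": 0.30, "a0": 57.75, "tc": 8.20},
    "PG/Chol (8:2)": {"k": 0.20, "a0": 41.42, "tc": 20.60},
    "PG/Chol (7:3)": {"k": 0.28, "a0": 15.32, "tc": 22.73},
    "PG/Chol (6:4)": {"k": None, "a0": 3.05, "tc": None},
}

#: 2H / 31P NMR summary: membrane -> dict of
#: Lc_star [Angstrom], avg_S [-], delta_sigma [ppm], each keyed by
#: ("with_il", "without_il").
NMR_ORDER = {
    "POPC": {
        "Lc_star": {"with_il": 10.5, "without_il": 11.8},
        "avg_S": {"with_il": 0.125, "without_il": 0.161},
        "delta_sigma": {"with_il": 63.9, "without_il": 45.9},
    },
    "POPC/Chol 9:1": {
        "Lc_star": {"with_il": 11.4, "without_il": 12.8},
        "avg_S": {"with_il": 0.151, "without_il": 0.198},
        "delta_sigma": {"with_il": 64.0, "without_il": 48.0},
    },
    "POPC/Chol 6:4": {
        "Lc_star": {"with_il": 13.0, "without_il": 14.9},
        "avg_S": {"with_il": 0.209, "without_il": 0.295},
        "delta_sigma": {"with_il": 63.0, "without_il": 43.0},
    },
    "POPG": {
        "Lc_star": {"with_il": 12.2, "without_il": 11.4},
        "avg_S": {"with_il": 0.152, "without_il": 0.148},
        "delta_sigma": {"with_il": 42.9, "without_il": 35.0},
    },
    "POPG/Chol 9:1": {
        "Lc_star": {"with_il": 11.9, "without_il": 13.0},
        "avg_S": {"with_il": 0.169, "without_il": 0.203},
        "delta_sigma": {"with_il": 43.0, "without_il": 38.0},
    },
    "POPG/Chol 6:4": {
        "Lc_star": {"with_il": 13.3, "without_il": 14.7},
        "avg_S": {"with_il": 0.224, "without_il": 0.280},
        "delta_sigma": {"with_il": 44.0, "without_il": 37.0},
    },
}

#: Monolayer lift-off areas, A^2/molecule.
LIFT_OFF_AREAS = {
    "ionic liquid (IL)": 15.0,
    "POPC": 111.0,
    "POPG": 132.0,
    "cholesterol": 48.0,
    "POPC/Chol = 80/20 mol %": 97.0,
    "POPC/Chol = 60/40 mol %": 84.0,
    "POPC/IL = 80/20 mol %": 107.0,
    "POPG/Chol = 80/20 mol %": 113.0,
    "POPG/Chol = 60/40 mol %": 90.0,
    "POPG/IL = 80/20 mol %": 124.0,
}

#: Excess Gibbs free energy over 0-30 mN/m, J/mol.
GIBBS_EXCESS = {
    "POPC/Chol = 80/20 mol %": -71.31,
    "POPC/Chol = 60/40 mol %": -86.38,
    "POPC/IL = 80/20 mol %": 254.63,
    "POPG/Chol = 80/20 mol %": -84.94,
    "POPG/Chol = 60/40 mol %": -156.44,
    "POPG/IL = 80/20 mol %": 381.94,
}

#: Molar mass of POPC, g/mol (for spread-film bookkeeping examples).
POPC_MOLAR_MASS = 760.08
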