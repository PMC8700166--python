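"""Independent literal transcriptions of the published equation formulas.

Deliberately naive scalar code, written straight from the printed formulas
with no shared machinery with the package implementation; used as the
second route in equation-equivalence tests.
"""

import math


def gfr_nmr_literal(age, female, cys, cre_umol, val, myo):
    if female:
        if cys < 1.02:
            intercept, e_cys = 238.0, -0.4114
        else:
            intercept, e_cys = 239.0, -0.6443
    else:
        if cys < 1.22:
            intercept, e_cys = 266.0, -0.5867
        else:
            intercept, e_cys = 269.0, -0.6419
    return (intercept * cys ** e_cys * cre_umol ** -0.3798 * val ** 0.1628
            * 0.9979 ** myo * 0.9963 ** age)


def ckd_epi_2009_literal(age, female, scr_mg_dl, black=False):
    kappa = 0.7 if female else 0.9
    alpha = -0.329 if female else -0.411
    out = (141.0 * min(scr_mg_dl / kappa, 1.0) ** alpha
           * max(scr_mg_dl / kappa, 1.0) ** -1.209 * 0.993 ** age)
    if female:
        out *= 1.018
    if black:
        out *= 1.159
    return out


def ckd_epi_cys_literal(age, female, scys):
    out = (133.0 * min(scys / 0.8, 1.0) ** -0.499
           * max(scys / 0.8, 1.0) ** -1.328 * 0.996 ** age)
    if female:
        out *= 0.932
    return out


def ckd_epi_crcys_literal(age, female, scr_mg_dl, scys, black=False):
    kappa = 0.7 if female else 0.9
    alpha = -0.248 if female else -0.207
    out = (135.0 * min(scr_mg_dl / kappa, 1.0) ** alpha
           * max(scr_mg_dl / kappa, 1.0) ** -0.601
           * min(scys / 0.8, 1.0) ** -0.375
           * max(scys / 0.8, 1.0) ** -0.711 * 0.995 ** age)
    if female:
        out *= 0.969
    if black:
        out *= 1.08
    return out


def ekfc_literal(age, female, scr_mg_dl):
    if age < 25:
        if female:
            lnq = (3.080 + 0.177 * age - 0.223 * math.log(age)
                   - 0.00596 * age ** 2 + 0.0000686 * age ** 3)
        else:
            lnq = (3.200 + 0.259 * age - 0.543 * math.log(age)
                   - 0.00763 * age ** 2 + 0.0000790 * age ** 3)
        q = math.exp(lnq) / 88.42
    else:
        q = 0.70 if female else 0.90
    r = scr_mg_dl / q
    alpha = 0.322 if r < 1.0 else 1.132
    out = 107.3 * r ** -alpha
    if age > 40:
        out *= 0.990 ** (age - 40)
    return out
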