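"""Built-in example inputs.

Two case tables (a multi-morbidity demonstration and the 1990 West
European injury-mortality data) and two directly specified multi-output
function systems used throughout the documentation and tests.
"""

from __future__ import annotations

import io

from .cases import CaseTable, read_cases_csv
from .truthtable import FunctionSpec, spec_from_minterms

__all__ = [
    "patient_groups",
    "injury_rates",
    "two_function_demo",
    "three_function_demo",
    "PATIENT_GROUPS_CSV",
    "INJURY_RATES_CSV",
]

#: Eleven patient groups: four socio-demographic inputs — g(ender),
#: i(ncome), f(amily history), m(arital status) — and two conditions,
#: a (diabetes) and e (depression).
PATIENT_GROUPS_CSV = """\
case,g,i,f,m,a,e
p1,1,0,1,1,1,1
p2,1,0,1,0,1,1
p3,0,1,0,0,0,0
p4,0,0,1,1,1,1
p5,1,1,1,0,1,1
p6,1,1,1,1,1,1
p7,1,0,0,1,0,1
p8,0,1,1,0,1,1
p9,0,0,0,0,1,1
p10,0,0,0,1,0,1
p11,0,1,0,1,0,1
"""

#: Injury rates in 12 West European countries (1990): five structural
#: inputs and two age-standardized death-rate outputs (motor vehicle
#: traffic accidents, suicides and self-inflicted injuries), all
#: dichotomized at study-specific limits.
INJURY_RATES_CSV = """\
country,gnp,mys,apac,unem,roca,mvta,ssii
Belgium,1,1,1,1,1,1,1
Denmark,1,1,1,1,0,0,1
Finland,1,1,0,0,0,0,1
France,1,1,1,1,1,1,1
Ireland,0,0,0,1,1,1,0
Italy,1,0,1,1,1,1,0
Netherlands,1,1,0,0,0,0,0
Norway,1,1,0,0,0,0,1
Portugal,0,0,1,0,1,1,0
Spain,0,0,1,1,1,1,0
Sweden,1,1,0,0,0,0,1
UK,1,1,0,0,0,0,0
"""


def patient_groups() -> CaseTable:
    return read_cases_csv(
        io.StringIO(PATIENT_GROUPS_CSV), ("g", "i", "f", "m"), ("a", "e")
    )


def injury_rates() -> CaseTable:
    return read_cases_csv(
        io.StringIO(INJURY_RATES_CSV),
        ("gnp", "mys", "apac", "unem", "roca"),
        ("mvta", "ssii"),
    )


def two_function_demo() -> FunctionSpec:
    """f1(x,y,z) = Σm(1,3,7), f2(x,y,z) = Σm(2,6,7); completely specified.

    The smallest system whose joint optimization differs from two
    separate runs: xyz is a shared prime implicant of the product f1·f2
    but prime for neither output alone.
    """
    return spec_from_minterms(3, {"f1": (1, 3, 7), "f2": (2, 6, 7)})


def three_function_demo() -> FunctionSpec:
    """Three functions of four inputs with rich cross-output sharing."""
    return spec_from_minterms(
        4,
        {
            "f1": (2, 3, 5, 7, 8, 9, 10, 11, 13, 15),
            "f2": (2, 3, 5, 6, 7, 10, 11, 14, 15),
            "f3": (6, 7, 8, 9, 13, 14, 15),
        },
    )
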