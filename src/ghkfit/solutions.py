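"""Ionic solutions as salt recipes.

Pipette and bath solutions are described the way they are mixed at the rig:
a list of salts with concentrations in mM. Per-ion totals, ionic strength and
ion activities are derived from the recipe. The built-in registry carries the
standard extracellular series (ES1–ES5), the two pipette solutions (I1, I2)
and the symmetric-NaCl dilution series (1 / 0.5 / 0.25 NaCl) used for
dilution-potential selectivity experiments.

Conventions
-----------
* Concentrations are mM everywhere; ionic strength is returned in M.
* Large organic substitutes (NMDG+, gluconate-) are charged but impermeant.
* Buffers, sugars, chelators and nucleotide salts (HEPES, glucose, sucrose,
  EGTA, BAPTA, Mg-ATP, Na-GTP, cGMP, cAMP) are modelled as single neutral
  formula units: they contribute neither to ion totals nor to ionic strength.
  Their charge states are pH-dependent and are not tracked.
* pH titrants (e.g. NaOH) are not part of the built-in recipes because the
  titrated amounts are unknown; an explicit NaOH component can be added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import yaml

__all__ = [
    "IonSpecies",
    "SaltComponent",
    "Solution",
    "ActivityModel",
    "ION_TABLE",
    "SALT_RECIPES",
    "salt",
    "build_solution",
    "ionic_strength",
    "activity",
    "dilution_series",
    "registry",
    "get_solution",
    "solutions_to_yaml",
    "solutions_from_yaml",
]


@dataclass(frozen=True)
class IonSpecies:
    """A dissolved species: name, signed charge, and whether a channel may pass it."""

    name: str
    charge: int
    permeant: bool = True


#: Known species. Charge 0 entries are whole neutral formula units.
ION_TABLE: dict[str, IonSpecies] = {
    "Na": IonSpecies("Na", +1),
    "K": IonSpecies("K", +1),
    "Ca": IonSpecies("Ca", +2),
    "Mg": IonSpecies("Mg", +2),
    "Cl": IonSpecies("Cl", -1),
    "NMDG": IonSpecies("NMDG", +1, permeant=False),
    "gluconate": IonSpecies("gluconate", -1, permeant=False),
    "OH": IonSpecies("OH", -1, permeant=False),
    "HEPES": IonSpecies("HEPES", 0, permeant=False),
    "glucose": IonSpecies("glucose", 0, permeant=False),
    "sucrose": IonSpecies("sucrose", 0, permeant=False),
    "EGTA": IonSpecies("EGTA", 0, permeant=False),
    "BAPTA": IonSpecies("BAPTA", 0, permeant=False),
    "MgATP": IonSpecies("MgATP", 0, permeant=False),
    "NaGTP": IonSpecies("NaGTP", 0, permeant=False),
    "cGMP": IonSpecies("cGMP", 0, permeant=False),
    "cAMP": IonSpecies("cAMP", 0, permeant=False),
}

#: Stoichiometry of the salts that appear in the built-in recipes.
SALT_RECIPES: dict[str, dict[str, int]] = {
    "NaCl": {"Na": 1, "Cl": 1},
    "KCl": {"K": 1, "Cl": 1},
    "CaCl2": {"Ca": 1, "Cl": 2},
    "MgCl2": {"Mg": 1, "Cl": 2},
    "NMDG-Cl": {"NMDG": 1, "Cl": 1},
    "K-gluconate": {"K": 1, "gluconate": 1},
    "Na-gluconate": {"Na": 1, "gluconate": 1},
    "NaOH": {"Na": 1, "OH": 1},
    "HEPES": {"HEPES": 1},
    "glucose": {"glucose": 1},
    "sucrose": {"sucrose": 1},
    "EGTA": {"EGTA": 1},
    "BAPTA": {"BAPTA": 1},
    "Mg-ATP": {"MgATP": 1},
    "Na-GTP": {"NaGTP": 1},
    "cGMP": {"cGMP": 1},
    "cAMP": {"cAMP": 1},
}


@dataclass(frozen=True)
class SaltComponent:
    """One salt of a recipe: name, concentration (mM) and ion counts per formula unit."""

    salt_name: str
    concentration_mM: float
    stoichiometry: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.concentration_mM < 0:
            raise ValueError(
                f"salt {self.salt_name!r}: concentration must be >= 0 mM, "
                f"got {self.concentration_mM}"
            )
        if not self.stoichiometry:
            raise ValueError(f"salt {self.salt_name!r}: empty stoichiometry")
        charge = 0
        for ion, count in self.stoichiometry.items():
            if ion not in ION_TABLE:
                raise ValueError(
                    f"salt {self.salt_name!r}: unknown species {ion!r} "
                    f"(known: {sorted(ION_TABLE)})"
                )
            if not (isinstance(count, int) and count > 0):
                raise ValueError(
                    f"salt {self.salt_name!r}: stoichiometric count for {ion!r} "
                    f"must be a positive integer, got {count!r}"
                )
            charge += ION_TABLE[ion].charge * count
        if charge != 0:
            raise ValueError(
                f"salt {self.salt_name!r} is not electroneutral "
                f"(net formula-unit charge {charge:+d})"
            )
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))


def salt(name: str, concentration_mM: float) -> SaltComponent:
    """Build a :class:`SaltComponent` for a salt known to :data:`SALT_RECIPES`."""
    try:
        stoich = SALT_RECIPES[name]
    except KeyError:
        raise ValueError(
            f"unknown salt {name!r}; known salts: {sorted(SALT_RECIPES)}"
        ) from None
    return SaltComponent(name, concentration_mM, stoich)


@dataclass(frozen=True)
class Solution:
    """A named ionic medium with derived per-ion totals (mM)."""

    name: str
    side: str  # "intracellular" | "extracellular"
    components: tuple[SaltComponent, ...]
    notes: tuple[str, ...] = ()
    ion_totals: Mapping[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.side not in ("intracellular", "extracellular"):
            raise ValueError(
                f"solution {self.name!r}: side must be 'intracellular' or "
                f"'extracellular', got {self.side!r}"
            )
        totals: dict[str, float] = {}
        for comp in self.components:
            for ion, count in comp.stoichiometry.items():
                totals[ion] = totals.get(ion, 0.0) + comp.concentration_mM * count
        object.__setattr__(self, "ion_totals", totals)

    def total(self, ion: str) -> float:
        """Total concentration of *ion* in mM (0 if absent)."""
        return self.ion_totals.get(ion, 0.0)

    def component(self, salt_name: str) -> SaltComponent | None:
        for comp in self.components:
            if comp.salt_name == salt_name:
                return comp
        return None


def build_solution(
    name: str,
    side: str,
    components: Iterable[SaltComponent],
    notes: Iterable[str] = (),
) -> Solution:
    """Assemble a :class:`Solution`; each component is validated on construction."""
    return Solution(name, side, tuple(components), tuple(notes))


def ionic_strength(solution: Solution) -> float:
    """Ionic strength I = 1/2 sum c_i z_i^2 in M, over all charged species."""
    acc = 0.0
    for ion, c_mM in solution.ion_totals.items():
        z = ION_TABLE[ion].charge
        acc += (c_mM / 1000.0) * z * z
    return 0.5 * acc


@dataclass(frozen=True)
class ActivityModel:
    """How concentrations map to activities.

    ``unity`` takes activity = concentration (the conventional default when no
    coefficient model is stated for a fit). ``davies`` applies the Davies
    equation log10(gamma) = -A z^2 (sqrt(I)/(1+sqrt(I)) - b*I) with the 25 °C
    constant A = 0.509 per sqrt(M) and linear coefficient b = 0.3.
    """

    mode: str = "unity"  # "unity" | "davies"
    davies_A: float = 0.509
    davies_linear: float = 0.3

    def __post_init__(self) -> None:
        if self.mode not in ("unity", "davies"):
            raise ValueError(f"unknown activity model mode {self.mode!r}")

    def coefficient(self, charge: int, ionic_strength_M: float) -> float:
        """Activity coefficient gamma in (0, 1]."""
        if self.mode == "unity" or charge == 0 or ionic_strength_M <= 0:
            return 1.0
        root = math.sqrt(ionic_strength_M)
        exponent = -self.davies_A * charge * charge * (
            root / (1.0 + root) - self.davies_linear * ionic_strength_M
        )
        return min(10.0**exponent, 1.0)


def activity(solution: Solution, ion: str, model: ActivityModel) -> float:
    """Activity of *ion* in *solution*, in mM."""
    if ion not in solution.ion_totals:
        raise ValueError(
            f"ion {ion!r} is not present in solution {solution.name!r} "
            f"(present: {sorted(solution.ion_totals)})"
        )
    c = solution.ion_totals[ion]
    gamma = model.coefficient(ION_TABLE[ion].charge, ionic_strength(solution))
    return gamma * c


def dilution_series(base: Solution, factors: Iterable[float]) -> list[Solution]:
    """Scale the NaCl component of *base* by each factor, other salts unchanged.

    Osmolarity lost with NaCl is balanced by adding sucrose (2 mM per mM NaCl
    removed), recorded in the solution notes; sucrose is inert here.
    """
    base_nacl = base.component("NaCl")
    if base_nacl is None:
        raise ValueError(f"solution {base.name!r} has no NaCl component to dilute")
    out: list[Solution] = []
    for f in factors:
        if not (0 < f <= 1):
            raise ValueError(f"dilution factor must be in (0, 1], got {f}")
        if f == 1:
            out.append(base)
            continue
        new_nacl = base_nacl.concentration_mM * f
        sucrose_mM = 2.0 * (base_nacl.concentration_mM - new_nacl)
        comps = [
            replace(c, concentration_mM=new_nacl) if c.salt_name == "NaCl" else c
            for c in base.components
        ]
        comps.append(salt("sucrose", sucrose_mM))
        out.append(
            build_solution(
                f"{f:g}NaCl" if base.name == "1NaCl" else f"{base.name}_x{f:g}",
                base.side,
                comps,
                notes=base.notes
                + (f"NaCl diluted x{f:g}; osmolarity balanced with {sucrose_mM:g} mM sucrose",),
            )
        )
    return out


def _builtin_solutions() -> dict[str, Solution]:
    ext = "extracellular"
    es1 = build_solution(
        "ES1",
        ext,
        [
            salt("NaCl", 150),
            salt("KCl", 5),
            salt("CaCl2", 1),
            salt("MgCl2", 4),
            salt("HEPES", 15),
            salt("glucose", 10),
        ],
        notes=("standard bath; pH 7.2 NaOH titrant excluded (amount unknown)",),
    )
    es2 = build_solution(
        "ES2",
        ext,
        [
            salt("NaCl", 15),
            salt("NMDG-Cl", 135),
            salt("KCl", 5),
            salt("CaCl2", 1),
            salt("MgCl2", 4),
            salt("HEPES", 15),
            salt("glucose", 10),
        ],
        notes=("low Na+: NMDG+ substitutes for Na+ at constant Cl-",),
    )
    es3_recipe = build_solution(
        "ES3_recipe",
        ext,
        [
            salt("NaCl", 30),
            salt("Na-gluconate", 120),
            salt("KCl", 5),
            salt("CaCl2", 1),
            salt("MgCl2", 4),
            salt("HEPES", 15),
            salt("glucose", 10),
        ],
        notes=("low Cl- as per the written recipe; Cl- total 45 mM",),
    )
    es3_legend = build_solution(
        "ES3_legend",
        ext,
        [
            salt("NaCl", 15),
            salt("Na-gluconate", 135),
            salt("KCl", 5),
            salt("CaCl2", 1),
            salt("MgCl2", 4),
            salt("HEPES", 15),
            salt("glucose", 10),
        ],
        notes=(
            "low Cl- reconstructed to the figure-legend totals "
            "(150 mM Na+, 30 mM Cl-); differs from ES3_recipe",
        ),
    )
    es4 = build_solution(
        "ES4",
        ext,
        [
            salt("NaCl", 15),
            salt("KCl", 140),
            salt("CaCl2", 1),
            salt("MgCl2", 4),
            salt("HEPES", 15),
            salt("glucose", 10),
        ],
        notes=("high K+: as ES2 with 140 mM KCl and no NMDG-Cl",),
    )
    es5 = build_solution(
        "ES5",
        ext,
        [
            salt("NaCl", 15),
            salt("NMDG-Cl", 85),
            salt("KCl", 5),
            salt("CaCl2", 25),
            salt("MgCl2", 4),
            salt("HEPES", 15),
            salt("glucose", 10),
        ],
        notes=("high Ca2+: as ES2 with 25 mM CaCl2, 85 mM NMDG-Cl",),
    )
    i1 = build_solution(
        "I1",
        "intracellular",
        [
            salt("K-gluconate", 115),
            salt("KCl", 25),
            salt("CaCl2", 0.5),
            salt("HEPES", 50),
            salt("Mg-ATP", 5),
            salt("Na-GTP", 0.5),
            salt("cGMP", 0.5),
            salt("cAMP", 0.5),
            salt("BAPTA", 1),
        ],
        notes=("pipette solution for the ES1–ES5 series; pH 7.4",),
    )
    i2 = build_solution(
        "I2",
        "intracellular",
        [
            salt("NaCl", 145),
            salt("CaCl2", 1),
            salt("MgCl2", 1),
            salt("EGTA", 1),
            salt("HEPES", 10),
            salt("glucose", 10),
        ],
        notes=("pipette solution for dilution-potential experiments; pH 7.2",),
    )
    nacl_ref = build_solution(
        "1NaCl",
        ext,
        [
            salt("NaCl", 145),
            salt("CaCl2", 1),
            salt("MgCl2", 1),
            salt("HEPES", 10),
        ],
        notes=("symmetric-NaCl control bath for dilution-potential experiments",),
    )
    half, quarter = dilution_series(nacl_ref, [0.5, 0.25])
    sols = {
        s.name: s
        for s in (es1, es2, es3_recipe, es3_legend, es4, es5, i1, i2, nacl_ref, half, quarter)
    }
    return sols


def registry() -> dict[str, Solution]:
    """Built-in solutions keyed by name (ES1–ES5 variants, I1, I2, dilution series)."""
    return _builtin_solutions()


def get_solution(name: str) -> Solution:
    sols = registry()
    try:
        return sols[name]
    except KeyError:
        raise ValueError(
            f"unknown solution {name!r}; available: {sorted(sols)}"
        ) from None


# ---------------------------------------------------------------------------
# Structured-text (YAML) interchange


def solutions_to_yaml(solutions: Iterable[Solution]) -> str:
    docs = []
    for s in solutions:
        docs.append(
            {
                "name": s.name,
                "side": s.side,
                "components": [
                    {
                        "salt": c.salt_name,
                        "mM": c.concentration_mM,
                        "stoichiometry": dict(c.stoichiometry),
                    }
                    for c in s.components
                ],
                "notes": list(s.notes),
            }
        )
    return yaml.safe_dump({"solutions": docs}, sort_keys=False)


def solutions_from_yaml(text: str) -> dict[str, Solution]:
    doc = yaml.safe_load(text)
    out: dict[str, Solution] = {}
    for entry in doc["solutions"]:
        comps = []
        for c in entry["components"]:
            stoich = c.get("stoichiometry") or SALT_RECIPES.get(c["salt"])
            if stoich is None:
                raise ValueError(
                    f"solution {entry['name']!r}: salt {c['salt']!r} needs an "
                    f"explicit stoichiometry (not a known salt)"
                )
            comps.append(SaltComponent(c["salt"], float(c["mM"]), stoich))
        sol = build_solution(
            entry["name"], entry["side"], comps, notes=entry.get("notes", ())
        )
        out[sol.name] = sol
    return out
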