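"""Shared fixtures: the default library/registry and the reference ion table.

``REFERENCE_IONS`` freezes the published LC-HRMS survey of the analogue
families: measured m/z of the protonated, ammoniated and sodiated ions,
retention time, elemental composition, and the registry composition each
row resolves to.  ``targeted`` marks the six rows whose ammoniated ions are
used for the strict 5 ppm agreement checks.
"""

from dataclasses import dataclass

import pytest

from depsimatch import CompoundRegistry, enumerate_compositions


@dataclass(frozen=True)
class ReferenceIon:
    label: str
    mz_proton: float
    mz_ammonium: float
    mz_sodium: float
    rt: float
    formula: str
    composition_key: str
    targeted: bool


REFERENCE_IONS: tuple[ReferenceIon, ...] = (
    ReferenceIon("BEA", 784.4144, 801.4426, 806.3947, 7.4,
                 "C45H57N3O9", "Hiv,Hiv,Hiv|161,161,161", True),
    ReferenceIon("BEA B/ALLOBEA B", 812.4446, 829.4738, 834.4267, 12.4,
                 "C47H61N3O9", "Hiv,Hmp,Hmp|161,161,161", True),
    ReferenceIon("BEA E", 736.4155, 753.4431, 758.3968, 6.4,
                 "C41H57N3O9", "Hiv,Hiv,Hiv|113,161,161", True),
    ReferenceIon("BEA G1", 770.3997, 787.4274, 792.3809, 7.0,
                 "C44H55N3O9", "Hbu,Hiv,Hiv|161,161,161", False),
    ReferenceIon("BEA G2", 756.3840, 773.4124, 778.3668, 6.7,
                 "C43H53N3O9", "Hbu,Hbu,Hiv|161,161,161", True),
    ReferenceIon("BEAE B", 688.4184, 705.4425, 710.3965, 6.3,
                 "C37H57N3O9", "Hiv,Hiv,Hiv|113,113,161", True),
    ReferenceIon("BEAE G1/G2/G3", 716.4469, 733.4745, 738.4263, 6.7,
                 "C39H61N3O9", "Hiv,Hiv,Hmp|113,127,161", False),
    ReferenceIon("BEAE *", 702.4344, 719.4581, 724.4130, 5.7,
                 "C38H59N3O9", "Hiv,Hiv,Hiv|113,127,161", True),
)

#: The six printed single-residue diagnostic losses (Da, nominal).
DIAGNOSTIC_LOSSES = {161, 127, 113, 100, 114, 86}


@pytest.fixture(scope="session")
def library():
    return enumerate_compositions()


@pytest.fixture(scope="session")
def registry():
    return CompoundRegistry.default()
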