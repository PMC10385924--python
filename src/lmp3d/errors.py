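"""Exception hierarchy for parsing, topology and unwrapping failures."""


class Lmp3dError(Exception):
    """Base class for all package errors."""


class MissingSection(Lmp3dError):
    """A required data-file section (e.g. Bonds) is absent."""

    def __init__(self, section: str):
        self.section = section
        super().__init__(f"required section missing from data file: {section!r}")


class MalformedRecord(Lmp3dError):
    """A data-file or dump line does not have the expected field count."""

    def __init__(self, line_no: int, expected: str, got: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: expected {expected}, got {got!r}")


class CountMismatch(Lmp3dError):
    """Header-declared count disagrees with the rows actually present."""

    def __init__(self, section: str, declared: int, found: int):
        self.section = section
        super().__init__(
            f"{section}: header declares {declared} rows but {found} were found"
        )


class MissingColumn(Lmp3dError):
    """A dump frame lacks a required column (id, mol, type or coordinates)."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"dump is missing required column: {column!r}")


class MixedCoordinateKinds(Lmp3dError):
    """Both wrapped (x) and unwrapped (xu) coordinates present in one dump."""


class ScaledCoordinatesUnsupported(Lmp3dError):
    """Scaled dump coordinates (xs/ys/zs) are rejected, not converted."""


class TruncatedFrame(Lmp3dError):
    """Dump ended mid-frame."""


class AtomSetMismatch(Lmp3dError):
    """Atom-id sets of data file and dump frame differ."""

    def __init__(self, only_data, only_dump):
        self.only_data = sorted(only_data)
        self.only_dump = sorted(only_dump)
        super().__init__(
            f"atom ids only in data file: {self.only_data[:10]}; "
            f"only in dump: {self.only_dump[:10]}"
        )


class UnknownMass(Lmp3dError):
    """Atomic mass matches neither an element nor the united-atom table."""

    def __init__(self, mass: float):
        self.mass = mass
        super().__init__(f"cannot assign an element to mass {mass} g/mol")


class DisconnectedMolecule(Lmp3dError):
    """A molecule's bond graph is not connected."""

    def __init__(self, mol_id: int, component_sizes):
        self.mol_id = mol_id
        self.component_sizes = sorted(component_sizes, reverse=True)
        super().__init__(
            f"molecule {mol_id}: bond graph has components of sizes "
            f"{self.component_sizes}"
        )


class NonOrthogonalBox(Lmp3dError):
    """Triclinic tilt factors are not supported for wrapped coordinates."""


class BondLongerThanHalfBox(Lmp3dError):
    """Minimum-image unwrapping is ambiguous; reported, never guessed."""

    def __init__(self, atom_i: int, atom_j: int, length: float, half_box: float):
        super().__init__(
            f"bond {atom_i}-{atom_j} unwraps to {length:.3f} A, longer than "
            f"half the shortest box side ({half_box:.3f} A): unwrapping ambiguous"
        )


class ZeroVolume(Lmp3dError):
    """Simulation box has zero volume; density undefined."""


class DegenerateWeights(Lmp3dError):
    """All atomic weights are zero for a non-charge weighting scheme."""


class SpecInvalid(Lmp3dError):
    """Fixture specification is not realisable."""
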