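"""Exception hierarchy for fetalbiom."""


class FetalBiomError(Exception):
    """Base class for all fetalbiom errors."""


class SchemaViolationError(FetalBiomError):
    """A label volume contains voxel values outside the declared schema."""

    def __init__(self, offending_values):
        self.offending_values = sorted(int(v) for v in offending_values)
        super().__init__(
            f"volume contains labels outside the schema: {self.offending_values}"
        )


class DegenerateMaskError(FetalBiomError):
    """A binary mask has too few foreground pixels for the operation."""


class MissingStructureError(FetalBiomError):
    """One or more required anatomical structures are absent."""

    def __init__(self, structures, detail=""):
        if isinstance(structures, str):
            structures = [structures]
        self.structures = list(structures)
        msg = f"missing structure(s): {', '.join(self.structures)}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class PhantomSpecError(FetalBiomError):
    """A phantom specification is geometrically inconsistent."""


class ConstantInputError(FetalBiomError):
    """A correlation is undefined because an input sequence is constant."""
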