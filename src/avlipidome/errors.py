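"""Exception hierarchy for the pipeline.

Parsing and quantification raise subclasses of :class:`AvLipidomeError`
so callers can distinguish schema problems (bad input files) from
computation problems (degenerate data).
"""


class AvLipidomeError(Exception):
    """Base class for all package-specific errors."""


class UnknownClass(AvLipidomeError):
    """Lipid class token not present in the subclass registry."""


class MalformedComposition(AvLipidomeError):
    """Shorthand composition (C:DB;On chunks) could not be parsed."""


class UnsupportedClassForFormula(AvLipidomeError):
    """Elemental composition rules cannot compose this subclass."""


class MissingIstd(AvLipidomeError):
    """No internal standard registered for a lipid subclass."""


class ZeroIstdArea(AvLipidomeError):
    """Internal-standard peak area is zero; the analyte ratio is undefined."""


class DegenerateDesign(AvLipidomeError):
    """Calibration amounts have no variance; regression is undefined."""


class ZeroDenominator(AvLipidomeError):
    """Denominator group mean is zero (recovery or ratio)."""


class InsufficientData(AvLipidomeError):
    """Too few observations for the requested statistical test."""


class UndefinedRatio(AvLipidomeError):
    """Ratio denominator total is zero in every sample."""


class MissingStage(AvLipidomeError):
    """A disease stage required for averaging is absent from the metadata."""


class AllMissingLipid(AvLipidomeError):
    """A lipid row has no observed value to impute from."""


class UnresolvedChains(AvLipidomeError):
    """Species-level sphingolipid cannot be decomposed into base and acyl."""


class EmptyPool(AvLipidomeError):
    """No decomposable sphingolipid species in the requested pool."""


class UnparsableStructure(AvLipidomeError):
    """Backbone structure string (SMILES) could not be parsed."""


class MissingFeature(AvLipidomeError):
    """A lipid lacks a structural feature required by the topology matrix."""


class UncoveredClass(AvLipidomeError):
    """A simulated subclass has no internal standard covering it."""


class SchemaError(AvLipidomeError):
    """An input table violates its documented header/key contract."""
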