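"""Exception hierarchy.

All library-raised errors derive from :class:`RuleForgeError` so callers can
catch one base type at the CLI boundary.
"""


class RuleForgeError(Exception):
    """Base class for all ruleforge errors."""


class ReactionParseError(RuleForgeError):
    """A reaction or molecule string could not be parsed."""


class MappingError(RuleForgeError):
    """Atom-map numbers violate the side-uniqueness invariant."""


class CofactorFileError(RuleForgeError):
    """A cofactor list file contains an unparseable entry."""


class PolicyError(RuleForgeError):
    """A run policy is internally inconsistent."""


class DiameterError(RuleForgeError):
    """Requested rule diameter is not an even non-negative integer."""


class NoPrimarySubstrateError(RuleForgeError):
    """Every substrate of a reaction is flagged as a cofactor."""


class StereoPerceptionError(RuleForgeError):
    """Stereo descriptors could not be perceived on a mapped atom."""


class NoReferenceScoreError(RuleForgeError):
    """Custom-rule scoring has no reference scores at the requested diameter."""


class ExportError(RuleForgeError):
    """Database export failed (duplicate rule key, unwritable path, ...)."""


class QueryError(RuleForgeError):
    """A database query filter is malformed."""
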