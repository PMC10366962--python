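"""Exception hierarchy for the screening engine.

Every error the engine raises derives from :class:`MedscreenError`, so
callers embedding the engine can catch one type at the boundary.
"""

from __future__ import annotations


class MedscreenError(Exception):
    """Base class for all errors raised by medscreen."""


class KBFormatError(MedscreenError):
    """A knowledge-base file could not be parsed.

    Carries the offending path and, when known, the line number.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)


class KBIntegrityError(MedscreenError):
    """The knowledge base violates a referential-integrity invariant.

    ``offenders`` lists each dangling or duplicated reference found.
    """

    def __init__(self, offenders: list[str]):
        self.offenders = list(offenders)
        super().__init__("knowledge-base integrity violation(s): " + "; ".join(self.offenders))


class UnmappedConceptError(MedscreenError):
    """A local concept code has no mapping to a canonical concept."""

    def __init__(self, local_code: str, vocabulary: str):
        self.local_code = local_code
        self.vocabulary = vocabulary
        super().__init__(f"no mapping for local concept {local_code!r} in vocabulary {vocabulary!r}")


class KnowledgeGapError(MedscreenError):
    """A prescribed concept has no required weight entry in the KB."""

    def __init__(self, kind: str, concept_id: str):
        self.kind = kind
        self.concept_id = concept_id
        super().__init__(f"knowledge gap: no {kind} entry for concept {concept_id!r}")


class UnitConversionError(MedscreenError):
    """No conversion factor exists between two dose units."""

    def __init__(self, from_unit: str, to_unit: str):
        self.from_unit = from_unit
        self.to_unit = to_unit
        super().__init__(f"no conversion factor from {from_unit!r} to {to_unit!r}")


class CaseValidationError(MedscreenError):
    """A patient-case JSON document failed schema validation.

    ``errors`` is a list of ``{"pointer": ..., "message": ...}`` records,
    one per violation, with JSON-pointer locations into the document.
    """

    def __init__(self, errors: list[dict]):
        self.errors = errors
        detail = "; ".join(f"{e['pointer']}: {e['message']}" for e in errors)
        super().__init__(f"invalid patient case: {detail}")


class QuerySyntaxError(MedscreenError):
    """A SPARQL query against the KB graph was malformed."""


class DomainError(MedscreenError):
    """An argument fell outside an operation's domain."""
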