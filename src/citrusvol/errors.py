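"""Exception hierarchy for citrusvol."""

from __future__ import annotations


class CitrusVolError(Exception):
    """Base class for all citrusvol errors."""


class ValidationError(CitrusVolError):
    """An input violates its physical or numeric domain."""


class DatabaseError(CitrusVolError):
    """A reference-data or fixture file fails schema validation."""


class UnknownTargetError(CitrusVolError, LookupError):
    """Pest/disease name not found in the target database."""

    def __init__(self, name: str, suggestions: list[str]):
        self.name = name
        self.suggestions = suggestions
        hint = f"; did you mean: {', '.join(suggestions)}?" if suggestions else ""
        super().__init__(f"unknown target {name!r}{hint}")


class UnknownProductError(CitrusVolError, LookupError):
    """Active ingredient not found in the product registry."""

    def __init__(self, name: str, suggestions: list[str]):
        self.name = name
        self.suggestions = suggestions
        hint = f"; did you mean: {', '.join(suggestions)}?" if suggestions else ""
        super().__init__(
            f"unknown active ingredient {name!r}{hint} "
            "(pass an explicit mode-of-action class to override)"
        )


class UnknownCultivarError(CitrusVolError, LookupError):
    """Cultivar not found in the cultivar-group registry."""

    def __init__(self, name: str, suggestions: list[str]):
        self.name = name
        self.suggestions = suggestions
        hint = f"; did you mean: {', '.join(suggestions)}?" if suggestions else ""
        super().__init__(
            f"unknown cultivar {name!r}{hint} "
            "(pass an explicit density group instead)"
        )
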