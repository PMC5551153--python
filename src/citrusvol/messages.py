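"""Warning-message registry.

Warnings travel through the package as stable identifiers and are rendered
to English text only at the presentation layer, so that translations can be
added without touching calculation code.
"""

from __future__ import annotations

MESSAGES: dict[str, str] = {
    "label_check": (
        "Check the technical data sheet of the product to verify if it is "
        "authorized for this use and/or if there are limits of maximum "
        "application volume rate or maximum dose."
    ),
    "no_authorized_products": "There are no authorized products against this pest.",
    "trunk_application": (
        "Applications against this disease should be carried out directly on "
        "the trunk and main branches."
    ),
    "bait_treatment": (
        "Some products are authorized only as bait treatment; apply as bait "
        "treatment where the label says so."
    ),
}


def render(identifier: str) -> str:
    """Return the English text for a warning identifier.

    Unknown identifiers are returned verbatim rather than raising, so that
    user-edited databases can carry free-text warnings.
    """
    return MESSAGES.get(identifier, identifier)
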