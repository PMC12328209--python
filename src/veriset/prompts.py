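"""Stage prompt templates.

One template per pipeline stage, each a structural re-creation (role +
named placeholders) rather than a fixed vendor prompt; all templates are
config-overridable.  The two claim templates double as the deterministic
claim grammar: the linking statement they contain ("is involved in") is
what the entity extractor looks for when mining claims back out of text.
Every placeholder must be filled before dispatch; rendering with a
missing or extra field raises.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

LINKING_PHRASES = (
    "are involved in",
    "is involved in",
    "is related to",
    "are related to",
)

_DEFAULT_GENERATION = """[stage:generation]
You are an expert biologist. Propose the single most prominent biological
process shared by the genes below, then explain each gene's contribution.
Genes: {genes}
Answer with the process name on the first line, a blank line, then the
analytical narrative."""

_DEFAULT_CLAIM_FROM_PROCESS = "{genes} is involved in {process}"

_DEFAULT_CLAIM_FROM_NARRATIVE = "{gene} is involved in {function}"

_DEFAULT_VERIFICATION_JUDGMENT = """[stage:verification_judgment]
Decide whether the claim below is Supported, Partially supported or
Refuted by the database evidence. Answer starting with the decision word.
Claim: {claim}
Function: {function}
Evidence:
{evidence}"""

_DEFAULT_MODIFICATION = """[stage:modification]
Revise or retain the process name for this gene set based on the
verification report. Prefer the best-supported database term. Answer with
the process name on the first line, a blank line, then the revised
narrative.
Genes: {genes}
Current name: {process}
Narrative:
{narrative}
Verification report:
{report}"""

_DEFAULT_SUMMARIZATION = """[stage:summarization]
Produce the final process name and a consolidated narrative for this gene
set, taking the narrative verification report into account. Answer with
the process name on the first line, a blank line, then the narrative.
Genes: {genes}
Current name: {process}
Narrative:
{narrative}
Report digest: {report_digest}"""


def _placeholders(template: str) -> set[str]:
    return {
        name
        for _, name, _, _ in string.Formatter().parse(template)
        if name is not None
    }


class PromptRenderError(ValueError):
    """A template was rendered with missing or unexpected placeholders."""


@dataclass
class StagePromptSet:
    """The six stage templates driving the pipeline."""

    generation: str = _DEFAULT_GENERATION
    claim_from_process: str = _DEFAULT_CLAIM_FROM_PROCESS
    verification_judgment: str = _DEFAULT_VERIFICATION_JUDGMENT
    modification: str = _DEFAULT_MODIFICATION
    claim_from_narrative: str = _DEFAULT_CLAIM_FROM_NARRATIVE
    summarization: str = _DEFAULT_SUMMARIZATION
    overrides: dict = field(default_factory=dict)

    def render(self, stage: str, **values: str) -> str:
        template = getattr(self, stage, None)
        if template is None:
            raise PromptRenderError(f"unknown stage template: {stage}")
        needed = _placeholders(template)
        given = set(values)
        if needed != given:
            raise PromptRenderError(
                f"template {stage!r} expects {sorted(needed)}, got {sorted(given)}"
            )
        return template.format(**values)
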