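"""Pluggable text-generation backends.

The pipeline only requires an object with an ``identifier`` and a
``generate(prompt, temperature)`` method that is deterministic at
temperature 0.  Offline runs use :class:`ScriptedBackend`, which replays
a transcript keyed by a digest of the fully rendered prompt; live
backends (an OpenAI-compatible endpoint, say) can be plugged in by
implementing the same protocol.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Protocol, runtime_checkable


def prompt_digest(prompt: str) -> str:
    """Stable key for a rendered prompt (sha256 hex)."""
    return hashlib.sha256(prompt.encode()).hexdigest()


@runtime_checkable
class LLMBackend(Protocol):
    identifier: str

    def generate(self, prompt: str, temperature: float = 0.0) -> str: ...


class TranscriptError(KeyError):
    """A scripted backend received a prompt absent from its transcript."""


class ScriptedBackend:
    """Replays a prompt-digest -> response map; byte-deterministic."""

    def __init__(self, transcript: dict[str, str], identifier: str = "scripted"):
        self.identifier = identifier
        self.transcript = dict(transcript)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScriptedBackend":
        data = json.loads(Path(path).read_text())
        return cls(data, identifier=f"scripted:{Path(path).name}")

    def generate(self, prompt: str, temperature: float = 0.0) -> str:
        digest = prompt_digest(prompt)
        try:
            return self.transcript[digest]
        except KeyError:
            raise TranscriptError(
                f"no scripted response for prompt digest {digest[:12]}…"
            ) from None


class EchoBackend:
    """Returns the prompt itself; handy for prompt-assembly tests."""

    identifier = "echo"

    def generate(self, prompt: str, temperature: float = 0.0) -> str:
        return prompt


class RecordingBackend:
    """Wraps a backend and records (digest -> response) pairs.

    Used by the fixture generator to turn any deterministic backend into
    a replayable transcript.
    """

    def __init__(self, inner: LLMBackend):
        self.identifier = f"recording({inner.identifier})"
        self.inner = inner
        self.transcript: dict[str, str] = {}

    def generate(self, prompt: str, temperature: float = 0.0) -> str:
        response = self.inner.generate(prompt, temperature)
        self.transcript[prompt_digest(prompt)] = response
        return response
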