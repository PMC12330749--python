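"""LLM backend contract and offline implementations.

Every model-dependent stage (paragraph filtering, BEL extraction, the
similarity judge, GraphRAG answering) talks to a backend through one
method::

    complete(prompt: str) -> str

Implementations here are offline and deterministic:

* :class:`ScriptedBackend` — replies from a fixed script, in order or
  keyed by a substring of the prompt; the test and demo workhorse.
* :class:`ReplayBackend` — a JSON cache keyed by prompt hash, for
  record/replay of live runs.

A live API client (OpenAI, etc.) is a thin class with the same method;
none is bundled, keeping the package importable and testable with no
credentials or network.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Protocol


class BackendError(RuntimeError):
    """Transport- or schema-level failure of an LLM backend."""


class LLMBackend(Protocol):
    def complete(self, prompt: str) -> str:
        """Return the model's raw text completion for ``prompt``."""
        ...


class ScriptedBackend:
    """Deterministic backend replying from a pre-written script.

    ``script`` entries are returned in order; alternatively ``keyed``
    maps a substring of the prompt to a reply (checked first).  Running
    past the end of the script raises :class:`BackendError` — a test
    that consumes more completions than scripted is a bug.
    """

    def __init__(
        self,
        script: list[str] | None = None,
        keyed: dict[str, str] | None = None,
        default: str | None = None,
    ) -> None:
        self.script = list(script or [])
        self.keyed = dict(keyed or {})
        self.default = default
        self.calls: list[str] = []
        self._pos = 0

    def complete(self, prompt: str) -> str:
        self.calls.append(prompt)
        for key, reply in self.keyed.items():
            if key in prompt:
                return reply
        if self._pos < len(self.script):
            reply = self.script[self._pos]
            self._pos += 1
            return reply
        if self.default is not None:
            return self.default
        raise BackendError(
            f"scripted backend exhausted after {self._pos} replies "
            f"({len(self.calls)} calls)"
        )


class FailingBackend:
    """Backend that always fails; for exercising error isolation."""

    def __init__(self, message: str = "backend unavailable") -> None:
        self.message = message

    def complete(self, prompt: str) -> str:
        raise BackendError(self.message)


def _prompt_key(prompt: str) -> str:
    return hashlib.sha256(prompt.encode("utf-8")).hexdigest()


class ReplayBackend:
    """Record/replay cache around another backend.

    In replay mode (no inner backend) a cache miss is an error, which
    guarantees cached runs are bit-reproducible; with an inner backend,
    misses are forwarded and recorded.
    """

    def __init__(self, cache_path: str | Path, inner: LLMBackend | None = None) -> None:
        self.cache_path = Path(cache_path)
        self.inner = inner
        self._cache: dict[str, str] = {}
        if self.cache_path.exists():
            self._cache = json.loads(self.cache_path.read_text())

    def complete(self, prompt: str) -> str:
        key = _prompt_key(prompt)
        if key in self._cache:
            return self._cache[key]
        if self.inner is None:
            raise BackendError(f"replay cache miss for prompt hash {key[:12]}")
        reply = self.inner.complete(prompt)
        self._cache[key] = reply
        self.cache_path.write_text(json.dumps(self._cache, indent=1, sort_keys=True))
        return reply


_KEEP_DROP_PROMPT = """\
You are screening paragraphs of a scientific article for a biological
relation-extraction pipeline. Answer KEEP if the paragraph contains
scientific narrative (results, methods, discussion of molecular
interactions); answer DROP if it is boilerplate such as references,
acknowledgments, funding or author contributions. Answer with the single
word KEEP or DROP.

Section: {section}
Paragraph:
{text}
"""


def request_keep_drop(backend: LLMBackend, paragraph) -> bool:
    """Ask a backend whether a paragraph should be kept (LLM filter mode)."""
    prompt = _KEEP_DROP_PROMPT.format(section=paragraph.section, text=paragraph.text)
    reply = backend.complete(prompt).strip().upper()
    if reply not in ("KEEP", "DROP"):
        raise BackendError(f"filter backend returned {reply!r}, expected KEEP or DROP")
    return reply == "KEEP"
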