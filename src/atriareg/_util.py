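"""Shared logging helpers."""

from __future__ import annotations

import logging

logger = logging.getLogger("atriareg")

_warned: set[str] = set()


def warn_once(key: str, message: str) -> None:
    """Log ``message`` at WARNING level only once per process per ``key``.

    Used for per-call-site diagnostics that would otherwise flood the log
    inside optimization loops (zero-variance NCC images, discarded
    non-finite objective cells, degenerate triangles).
    """
    if key not in _warned:
        _warned.add(key)
        logger.warning(message)


def reset_warnings() -> None:
    _warned.clear()
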