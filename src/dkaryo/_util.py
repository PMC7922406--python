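"""Shared helpers: structured logging and stable checksums."""

from __future__ import annotations

import hashlib
import logging

log = logging.getLogger("dkaryo")


def setup_logging(level: int = logging.INFO) -> None:
    """Configure stderr logging for CLI use (library users configure their own)."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("dkaryo")
    root.handlers[:] = [handler]
    root.setLevel(level)


def digest_lines(lines) -> str:
    """sha1 hex digest over an iterable of text lines (canonical serialization)."""
    h = hashlib.sha1()
    for line in lines:
        h.update(line.encode())
        h.update(b"\n")
    return h.hexdigest()
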