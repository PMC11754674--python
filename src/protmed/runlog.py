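"""JSON-lines run logging.

The pipeline appends one JSON object per event (reader counts, clumping
drops, rule traces) to a run log.  By default events go to the standard
``logging`` channel; :func:`attach_file` redirects them to a file so a
screen run leaves a machine-readable audit trail.
"""

from __future__ import annotations

import json
import logging
import threading
import time

_logger = logging.getLogger("protmed")
_lock = threading.Lock()
_file_handle = None


def attach_file(path):
    """Send subsequent events to ``path`` (JSON lines, append mode)."""
    global _file_handle
    with _lock:
        if _file_handle is not None:
            _file_handle.close()
        _file_handle = open(path, "a")


def detach_file():
    global _file_handle
    with _lock:
        if _file_handle is not None:
            _file_handle.close()
            _file_handle = None


def log_event(event: str, **fields):
    """Record a structured event with a wall-clock timestamp."""
    record = {"event": event, "time": time.time(), **fields}
    line = json.dumps(record, default=str)
    with _lock:
        if _file_handle is not None:
            _file_handle.write(line + "\n")
            _file_handle.flush()
        else:
            _logger.debug(line)
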