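"""Longest-consecutive-run selection over per-B-scan classifications.

A fovea classifier scanning an eyecup raster occasionally fires on
peripheral B-scans, but the true fovea produces one consecutive block of
positives.  Keeping only the longest run of positive B-scans and taking
its central image is the false-positive filter applied before any
localization is attempted.

Tie-breaks (both documented choices): among equal-longest runs the
earliest wins; for an even-length run the centre is the lower middle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import NoFoveaError, ParameterError


@dataclass(frozen=True)
class RunSelection:
    """A maximal run of positive B-scans and its central image index."""

    run_start: int
    run_end: int  # inclusive
    central_index: int
    run_length: int


def select_central(flags: Sequence[bool]) -> RunSelection:
    """Select the central image of the longest run of positive flags.

    Parameters
    ----------
    flags
        Per-B-scan fovea classifications, in acquisition order.

    Raises
    ------
    ParameterError
        If ``flags`` is empty.
    NoFoveaError
        If no flag is positive (sampling must abort).
    """
    flags = [bool(f) for f in flags]
    if len(flags) == 0:
        raise ParameterError("flags: must be non-empty")

    best_start = best_len = -1
    start = None
    for i, f in enumerate(flags + [False]):  # sentinel terminates a final run
        if f and start is None:
            start = i
        elif not f and start is not None:
            length = i - start
            if length > best_len:  # strict: earliest run wins ties
                best_start, best_len = start, length
            start = None

    if best_len < 1:
        raise NoFoveaError("no positive B-scan in the stack")
    return RunSelection(
        run_start=best_start,
        run_end=best_start + best_len - 1,
        central_index=best_start + (best_len - 1) // 2,
        run_length=best_len,
    )
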