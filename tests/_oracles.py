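"""Independent reference implementations used only to check the package.

Deliberately written with different algorithms from the library code:
the repeat oracle extends every candidate start position character by
character; the lattice oracle is an exhaustive grid search; the
Boulder-IO parser is a from-scratch reader of the key=value record
format.
"""

from __future__ import annotations

import numpy as np


def _primitive(motif: str) -> bool:
    n = len(motif)
    return not any(n % d == 0 and motif == motif[:d] * (n // d) for d in range(1, n))


def brute_force_ssrs(seq: str, min_repeats: dict[int, int]) -> list[tuple]:
    """Every maximal perfect repeat, by per-start extension.

    Returns tuples (start, end, period, motif, repeat_count) sorted by
    (start, period), with primitive motifs only (smallest-period rule).
    """
    n = len(seq)
    found = []
    for p in (2, 3, 4):
        for start in range(n - p):
            # left-maximal: extension by one base breaks perfection
            if start > 0 and seq[start - 1] != "N" and seq[start - 1] == seq[start + p - 1]:
                continue
            motif = seq[start : start + p]
            if "N" in motif or not _primitive(motif):
                continue
            end = start + p
            while end < n and seq[end] != "N" and seq[end] == seq[end - p]:
                end += 1
            count = (end - start) // p
            if count >= min_repeats[p]:
                found.append((start, end, p, motif, count))
    found.sort(key=lambda t: (t[0], t[2]))
    return found


def grid_fit_offset(sizes, period: int, step: float = 0.001) -> tuple[float, float]:
    """Exhaustive grid search for the least-squares lattice offset."""
    offsets = np.arange(0.0, period, step)
    r = np.asarray(sizes, dtype=float) % period
    d = (r[None, :] - offsets[:, None] + period / 2.0) % period - period / 2.0
    ss = (d * d).sum(axis=1)
    i = int(ss.argmin())
    return float(offsets[i]), float(ss[i])


def circular_offset_distance(a: float, b: float, period: int) -> float:
    d = abs(a - b) % period
    return min(d, period - d)


def parse_boulder(text: str) -> list[dict[str, str]]:
    """Minimal Boulder-IO reader: key=value lines, '=' record terminator."""
    records: list[dict[str, str]] = []
    current: dict[str, str] = {}
    for line in text.splitlines():
        if line == "=":
            records.append(current)
            current = {}
        elif line:
            key, value = line.split("=", 1)
            current[key] = value
    if current:
        raise ValueError("unterminated Boulder-IO record")
    return records
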