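"""Small report arithmetic shared by the pipeline summary and reanalyses.

These helpers turn printed count tables (up/down events, gene totals,
per-nucleotide frequencies) into the derived percentages a study report
quotes.
"""

from __future__ import annotations


def percent_excess(n_up: int, n_down: int) -> float:
    """How many percent more up- than down-events: 100 * (up - down) / down."""
    if n_down <= 0:
        raise ValueError("reference count must be positive")
    return 100.0 * (n_up - n_down) / n_down


def percent_of_total(part: int, total: int) -> float:
    """Share of a total, in percent."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * part / total


def purine_share(freq_a: float, freq_g: float) -> float:
    """Combined A+G start share; accepts fractions or percent."""
    return freq_a + freq_g
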