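"""Audiogram line chart in the audiological convention.

Frequency on a log-scaled x axis, hearing level in dB HL on an inverted y
axis (larger losses plotted downward). Cosmetic visual check of entered
data, nothing more.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .core import Audiogram, PatientRecord, format_frequency


def plot_audiograms(
    record: PatientRecord,
    path: str | Path,
    normative: Audiogram | None = None,
) -> None:
    """Plot the acute audiogram against every available baseline."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    series: list[tuple[str, Audiogram, dict]] = [
        ("acute", record.acute, {"color": "crimson", "marker": "o"})
    ]
    if record.baseline_previous is not None:
        series.append(("previous", record.baseline_previous, {"color": "steelblue", "marker": "s"}))
    if record.baseline_contralateral is not None:
        series.append(
            ("contralateral", record.baseline_contralateral, {"color": "seagreen", "marker": "^"})
        )
    if normative is not None:
        series.append(("normative", normative, {"color": "gray", "linestyle": "--", "marker": "."}))
    for label, ag, style in series:
        freqs = list(ag.frequencies)
        ax.plot(freqs, [ag[f] for f in freqs], label=label, **style)
    ax.set_xscale("log")
    ticks = sorted({f for _, ag, _ in series for f in ag.frequencies})
    ax.set_xticks(ticks)
    ax.set_xticklabels([format_frequency(f) for f in ticks])
    ax.minorticks_off()
    ax.set_xlabel("Frequency (kHz)")
    ax.set_ylabel("Hearing level (dB HL)")
    ax.set_ylim(120, -10)  # inverted: worse hearing plotted downward
    ax.grid(True, alpha=0.3)
    ax.legend(loc="lower left", fontsize=8)
    title = record.id or "audiogram"
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
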