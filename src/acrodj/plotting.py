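"""Minimal plotting helpers (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .align import IdentityProfile


def plot_identity_profile(profile: IdentityProfile, path: str | Path,
                          ylim: tuple[float, float] = (80.0, 100.5)) -> None:
    """Per-window identity of each query along the reference, plus the mean."""
    fig, ax = plt.subplots(figsize=(8, 3))
    mids = [(s + e) / 2 / 1000 for s, e in profile.windows]
    for qid in profile.identities.columns:
        ax.plot(mids, profile.identities[qid], alpha=0.5, lw=1, label=qid)
    ax.plot(mids, profile.mean_identity, color="black", lw=2, label="mean")
    ax.set_xlabel(f"position on {profile.reference_id} (kb)")
    ax.set_ylabel("% identity")
    ax.set_ylim(*ylim)
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
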