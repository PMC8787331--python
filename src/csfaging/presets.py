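"""Synthetic stand-in coefficient tables for the four published clocks.

The real Horvath, Hannum, Levine (PhenoAge) and Zhang coefficient tables are
distributed with their respective publications and are not redistributed here.
These generators emit *synthetic* tables with the published structure — the
correct probe counts (353, 71, 513 and 514 CpG sites respectively), CpG-style
probe IDs, an ``"(Intercept)"`` sentinel row, and each clock's output
convention (Horvath's age anti-transformation; Zhang's within-sample
standardisation) — so that the loading, intersection and scoring machinery can
be exercised end to end.  The coefficients themselves are random draws and
carry no biological meaning; a real coefficient CSV in the same two-column
format drops in via :func:`csfaging.clocks.load_clock_table` unchanged.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from csfaging.clocks import INTERCEPT_SENTINEL, ClockDefinition, load_clock_table

__all__ = ["CLOCK_PRESETS", "synthetic_clock_table", "write_synthetic_clock_table", "load_synthetic_clock"]

#: name -> (probe count, transform, standardize_per_sample, intercept)
CLOCK_PRESETS: dict[str, tuple[int, str, bool, float]] = {
    "horvath": (353, "horvath_inverse", False, 0.696),
    "hannum": (71, "identity", False, 0.0),
    "levine": (513, "identity", False, 60.664),
    "zhang": (514, "identity", True, 65.8),
}


def synthetic_clock_table(name: str, seed: int = 0) -> pd.DataFrame:
    """Synthetic coefficient table (probe_id, coefficient) for a named preset.

    Probe IDs are deterministic ``cg``-style identifiers; coefficients are
    N(0, 0.5) draws (synthetic — see module docstring).
    """
    if name not in CLOCK_PRESETS:
        raise KeyError(f"unknown clock preset {name!r}; known: {sorted(CLOCK_PRESETS)}")
    n_probes, _, _, intercept = CLOCK_PRESETS[name]
    rng = np.random.default_rng([seed, abs(hash(name)) % (2**31)])
    # deterministic, unique cg IDs namespaced per clock
    offset = {"horvath": 0, "hannum": 1_000_000, "levine": 2_000_000, "zhang": 3_000_000}[name]
    probe_ids = [f"cg{offset + i:08d}" for i in range(n_probes)]
    coeffs = rng.normal(0.0, 0.5, size=n_probes)
    table = pd.DataFrame({"probe_id": probe_ids, "coefficient": coeffs})
    table.loc[len(table)] = [INTERCEPT_SENTINEL, intercept]
    return table


def write_synthetic_clock_table(name: str, path: str | Path, seed: int = 0) -> Path:
    """Write the synthetic preset table as a loadable coefficient CSV."""
    path = Path(path)
    synthetic_clock_table(name, seed=seed).to_csv(path, index=False)
    return path


def load_synthetic_clock(name: str, directory: str | Path, seed: int = 0) -> ClockDefinition:
    """Write then load a synthetic preset, returning its :class:`ClockDefinition`.

    Goes through the CSV round trip on purpose so the documented file contract
    is exercised, not bypassed.
    """
    n_probes, transform, standardize, _ = CLOCK_PRESETS[name]
    path = write_synthetic_clock_table(name, Path(directory) / f"{name}_synthetic_coefficients.csv", seed=seed)
    clock = load_clock_table(path, name=name, transform=transform, standardize_per_sample=standardize)
    assert clock.n_probes == n_probes
    return clock
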