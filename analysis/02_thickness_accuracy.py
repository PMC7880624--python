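#!/usr/bin/env python
"""Accuracy of echo-based pellet thickness on simulated noisy measurements.

Simulates 20 measurement pairs of a 1.000 mm slab (n = 1.8, quadratic
absorption reaching 80 cm^-1 at 1.4 THz, one etalon echo, SNR 10^3 at
1 THz) and recovers thickness from the re-reflected-pulse delay,
d = c*dt/(2n).  Finding: mean absolute error ~2.7 um (within the ~3 um
quoted for the technique), and the extraction run with that echo-estimated
thickness keeps the refractive-index error well under 1%.

A second block adds linear dispersion (dn/df = -0.02/THz): the echo then
travels at the group velocity of its low-pass-filtered spectrum, and the
same estimator acquires a ~+10 um systematic bias at d = 1 mm — the echo
delay measures the group index, not the 1 THz phase index.
"""

from pathlib import Path

import numpy as np

from thzpellet import (
    MaterialModel,
    NoiseSpec,
    PulseSpec,
    make_reference_pulse,
    simulate_measurement,
    thickness_from_echo,
)
from thzpellet.extraction import ExtractionConfig, extract_pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

D_TRUE = 1.0
BAND = (0.3, 1.2)


def experiment(material: MaterialModel, label: str, rows: list[str]) -> None:
    ref = make_reference_pulse(PulseSpec())
    config = ExtractionConfig(thickness_source="echo")
    d_err, n_err = [], []
    for seed in range(1, 21):
        pair = simulate_measurement(
            ref, material, D_TRUE, NoiseSpec(1e3, seed=seed), n_echoes=1
        )
        d_hat = thickness_from_echo(pair.sample, 1.8)
        d_err.append((d_hat - D_TRUE) * 1e3)
        props = extract_pipeline(pair, config=config)
        f = props.frequencies
        mask = (f >= BAND[0]) & (f <= BAND[1])
        n_true = material.n_of(f[mask])
        n_err.append(100 * np.max(np.abs(props.n[mask] - n_true) / n_true))
    mae = float(np.mean(np.abs(d_err)))
    bias = float(np.mean(d_err))
    print(
        f"{label}: thickness MAE {mae:.2f} um (bias {bias:+.2f} um), "
        f"max n error with echo-d {np.mean(n_err):.3f}% (worst {np.max(n_err):.3f}%)"
    )
    rows.append(f"{label}\t{mae:.3f}\t{bias:+.3f}\t{np.mean(n_err):.4f}")


def main() -> None:
    rows = ["case\tthickness_mae_um\tthickness_bias_um\tmean_max_n_err_pct"]
    experiment(
        MaterialModel(1.8, 0.0, (0.0, 0.0, 80 / 1.4**2)), "non-dispersive", rows
    )
    experiment(
        MaterialModel(1.8, -0.02, (0.0, 0.0, 80 / 1.4**2)), "dispersive(-0.02/THz)", rows
    )
    (RESULTS / "thickness_accuracy.tsv").write_text("\n".join(rows) + "\n")
    print(f"wrote {RESULTS / 'thickness_accuracy.tsv'}")


if __name__ == "__main__":
    main()
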