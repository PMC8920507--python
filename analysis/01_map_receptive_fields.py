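"""Phase 1: map receptive fields of the preset model neurons with pixel noise.

For each preset neuron, runs the pixel white-noise protocol, computes the
spike-triggered average, selects the peak frame (chi-square test), and
attempts to yoke significant pixels into two chromatically distinct
subfields.  Writes a summary table to results/rf_mapping.csv and STA
peak-frame images to results/figures/.

Expected outcome: the linear and rectified presets yield two subfields that
match the generating model; the energy preset (zero expected STA) is passed
over, mirroring the screening rule for cells without a two-subfield STA.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from v1iso.display import gaussian_phosphor_display
from v1iso.neurons import PRESETS, make_neuron, simulate_white_noise
from v1iso.stimulus import pixel_white_noise
from v1iso import receptive_field as rf

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_FRAMES = 50_000


def main(seed: int = 1) -> None:
    (RESULTS / "figures").mkdir(parents=True, exist_ok=True)
    display = gaussian_phosphor_display()
    rows = []
    for preset in PRESETS:
        neuron = make_neuron(preset)
        movie = pixel_white_noise(N_FRAMES, display, seed=seed, grid=neuron.grid)
        spikes = simulate_white_noise(neuron, movie, seed=seed + 1)
        sta = rf.compute_sta(movie, spikes, display)
        peak, significant = rf.select_peak_frame(sta)
        row = {
            "preset": preset,
            "n_spikes": int(spikes.sum()),
            "peak_frame": peak,
            "peak_latency_frames": 14 - peak,
            "peak_significant": significant,
        }
        try:
            hmap = rf.yoke_hyperpixels(sta, peak)
            truth = neuron.hmap
            found = set(hmap.subfield1) | set(hmap.subfield2)
            true_px = set(truth.subfield1) | set(truth.subfield2)
            row.update(
                status="yoked",
                n_pixels_sf1=len(hmap.subfield1),
                n_pixels_sf2=len(hmap.subfield2),
                jaccard_vs_truth=len(found & true_px) / len(found | true_px),
            )
        except rf.InsufficientSubfieldsError as exc:
            row.update(status="passed_over", note=str(exc))
        rows.append(row)

        fig, ax = plt.subplots(figsize=(3, 3))
        img = sta.frames[peak].reshape(*sta.grid, 3)
        scale = np.abs(img).max() or 1.0
        ax.imshow(0.5 + img / (2 * scale))
        ax.set_title(f"{preset}\nSTA peak frame {peak}")
        ax.set_xticks([]), ax.set_yticks([])
        fig.savefig(RESULTS / "figures" / f"sta_{preset}.png", dpi=120,
                    bbox_inches="tight")
        plt.close(fig)

    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "rf_mapping.csv", index=False)
    print(df.to_string(index=False))
    n_yoked = (df.status == "yoked").sum()
    print(
        f"\n{n_yoked}/{len(df)} presets yoked into two subfields. "
        "The energy preset has a zero expected STA (non-significant peak "
        "frame): any yoking there groups chance pixels, and its low Jaccard "
        "overlap with the generating subfields flags it as spurious."
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
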