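"""Validate depth-ratio CNV detection against the embedded events.

Runs the caller twice: on a low-noise cohort (150x mean depth, tight
negative-binomial dispersion) to measure best-case recall and false-call
rate, and on the default realistic-noise cohort to show how specificity
degrades with coverage dispersion.

Run from the repository root:  python analysis/03_call_cnvs.py
"""

from pathlib import Path

from triomode.cnv_depth_caller import calls_to_frame
from triomode.synthetic_cohort import SimulationConfig
from triomode.workflows import cnv_validation
from triomode import io

OUT = Path("results/cnv")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    common = dict(n_trios=500, n_genes=150, n_intervals=600,
                  background_variants_per_trio=0, de_novo_background_per_trio=0,
                  seed=SEED)
    low = cnv_validation(SimulationConfig(
        mean_depth=150.0, depth_dispersion=2000.0, interval_log_sd=0.05, **common))
    io.write_tsv(calls_to_frame(low.pop("calls")), OUT / "cnv_calls_low_noise.tsv")
    print(f"low-noise cohort ({low['n_trios']} trios, {low['n_events']} embedded events):")
    print(f"  recall {low['recall']:.3f}, false calls per trio "
          f"{low['false_calls_per_trio']:.3f}")

    default = cnv_validation(SimulationConfig(**common))
    io.write_tsv(calls_to_frame(default.pop("calls")), OUT / "cnv_calls_default_noise.tsv")
    print(f"default-noise cohort ({default['n_events']} events): "
          f"recall {default['recall']:.3f}, false calls per trio "
          f"{default['false_calls_per_trio']:.3f}")
    print("depth-ratio CNV detection is sensitive at low noise; specificity "
          "is the binding constraint as dispersion grows")
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
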