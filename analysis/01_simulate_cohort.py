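#!/usr/bin/env python
"""Simulate the study: design arithmetic and one example subject's data.

Writes the example subject's event table and ground-truth JSON under
results/simulation/ (one simulated BOLD run, a large binary NIfTI, goes
under scratch/), and prints the design arithmetic every later stage relies
on: 16 stimulus + 4 blank trials per run, 42 volumes x 2.72 s = 114.24 s
per run.
"""

from pathlib import Path

from avmvpa import synth
from avmvpa.pipeline import Config, simulate_subject

OUT = Path("results/simulation")
SCRATCH = Path("scratch/simulation")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = Config()  # 15 subjects, 18 runs, V2 noise modulation
    geometry, design, truth, patterns = simulate_subject(config, subject=0)

    spec = design.spec
    ev = design.run_events(0)
    print(f"runs per subject:        {spec.n_runs}")
    print(f"stimulus trials per run: {(ev.stimulus >= 0).sum()}")
    print(f"blank trials per run:    {(ev.stimulus < 0).sum()}")
    print(f"volumes per run:         {spec.volumes_per_run} "
          f"({spec.n_dummy_start}+{spec.n_dummy_end} dummies)")
    print(f"run duration:            {spec.run_duration:.2f} s")
    print("pattern-noise SD per condition (V2 analogue):",
          truth.noise_sd["V2"])

    design.to_tsv(OUT / "sub-00_events.tsv")
    truth.to_json(OUT / "sub-00_ground_truth.json")
    SCRATCH.mkdir(parents=True, exist_ok=True)
    runs = synth.generate_bold_runs(
        truth, design, geometry, noise_sd_ts=config.noise_sd_ts, seed=1,
        patterns=patterns,
    )
    synth.write_run(runs[0], SCRATCH / "sub-00_run-00_bold.nii.gz",
                    OUT / "sub-00_run-00_events.tsv")
    print(f"wrote example subject tables to {OUT}/ (BOLD NIfTI in {SCRATCH}/)")


if __name__ == "__main__":
    main()
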