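"""Benchmark the four denoisers over a grid of Gaussian noise variances.

Reproduces the comparison experiment on a reduced grid (256 px, 3 seeds,
3 variances) so it runs in under a minute; the full published grid is the
CLI default (`ctdenoise benchmark --out DIR`). Mean PSNR per cell is
printed: higher is better, and every method degrades as noise grows.
"""

from ctdenoise import run_benchmark

grid = run_benchmark(
    noise_kind="gaussian",
    levels=[0.02, 0.06, 0.10],
    methods=["q1", "q2", "q4", "q5"],
    seeds=[101, 202, 303],
    size=256,
)
print("mean PSNR (dB) per method and noise variance")
print(f"{'variance':>10s}" + "".join(f"{m:>14s}" for m in grid.methods))
for level in grid.levels:
    row = "".join(f"{grid.mean_metric(m, level, 'psnr'):14.2f}" for m in grid.methods)
    print(f"{level:>10.2f}{row}")
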