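"""Inter- and intra-observer reproducibility of the measurement.

Two simulated observers analyse the same noisy disc three times each,
clicking slightly different seed pixels.  The repeat standard deviations
quantify how sensitive the semi-automatic pipeline is to the click.
"""

from discsig import (
    PhantomSpec,
    compute_all,
    generate_disc_phantom,
    nucleus_seed_pixel,
    reproducibility_sd,
)

spec = PhantomSpec(intensity_gradient=0.15, noise_sigma=3.5, rng_seed=21)
slc, _ = generate_disc_phantom(spec)
r, c = nucleus_seed_pixel(spec)

clicks = {
    "observer1": [(r, c), (r + 2, c - 1), (r - 1, c + 2)],
    "observer2": [(r + 1, c + 1), (r - 2, c), (r, c - 2)],
}
repeats = {obs: [compute_all(slc, s) for s in seeds]
           for obs, seeds in clicks.items()}

result = reproducibility_sd(repeats)
print("pooled repeat SD over all 6 analyses:")
for key, val in result.pooled.items():
    if key != "n":
        print(f"  {key:8s} {val:.4f}")
for obs, sds in result.per_observer.items():
    print(f"{obs}: SD(DX) {sds['DX_mm']:.4f} mm, SD(PSM) {sds['PSM_mm']:.4f} mm")
print()
print("Near-zero SDs mean the region growing converges to the same nucleus")
print("outline wherever inside the bright zone the observer clicks, so the")
print("parameters are effectively click-independent (SM is reported as a")
print("percent coefficient of variation because its units are scanner-")
print("arbitrary).")
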