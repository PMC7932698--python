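#!/usr/bin/env python
"""Generate the synthetic study inputs for all downstream analyses.

Writes TIFF/CSV inputs plus JSON ground-truth sidecars under
results/inputs/. All later scripts read these files, so the whole
analysis chain runs off disk exactly as it would for real microscope
and trap exports.
"""

from pathlib import Path

from condensate_quant import io, synthetic

SEED = 0
OUT = Path("results/inputs")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # DNA curtain kymogram: dye channel, 2 px/frame compaction
    kspec = synthetic.SyntheticKymogramSpec(
        compaction_rate_v=2.0, association_rate_kappa=0.05,
        dna_intensity=1.0, noise_sigma=0.1, seed=SEED,
    )
    kym, truth = synthetic.gen_kymogram(kspec)
    io.write_tiff(OUT / "kymogram.tif", kym.intensity)
    io.write_json(OUT / "kymogram_truth.json", {
        "compaction_rate_v": kspec.compaction_rate_v,
        "association_rate_kappa": kspec.association_rate_kappa,
        "end_position": truth["end_position"],
    })

    # dye-only kymogram (intercalator at equilibrium, no net association):
    # the conservation statistic applies to this channel
    dye = synthetic.SyntheticKymogramSpec(
        compaction_rate_v=2.0, association_rate_kappa=0.0,
        dna_intensity=1.0, noise_sigma=0.05, n_frames=60, seed=SEED,
    )
    k, t = synthetic.gen_kymogram(dye)
    io.write_tiff(OUT / "kymogram_dye.tif", k.intensity)
    io.write_json(OUT / "kymogram_dye_truth.json",
                  {"end_position": t["end_position"]})

    # binding-kinetics kymograms (protein channel): equal vs blocked
    for mode in ("equal", "blocked"):
        spec = synthetic.SyntheticKymogramSpec(
            compaction_rate_v=2.0, association_rate_kappa=0.05,
            dna_intensity=0.0, binding_mode=mode, noise_sigma=0.02,
            n_frames=50, seed=SEED,
        )
        k, t = synthetic.gen_kymogram(spec)
        io.write_tiff(OUT / f"kymogram_{mode}.tif", k.intensity)
        io.write_json(OUT / f"kymogram_{mode}_truth.json",
                      {"end_position": t["end_position"], "mode": mode})

    # brightfield droplet fields: 3 images x 4 protein concentrations,
    # radius scaling ~ c^0.4
    layouts = [(40, 40), (120, 180), (190, 70), (60, 200), (200, 200)]
    for conc in (5.0, 10.0, 25.0, 50.0):
        base = 3.0 * (conc / 5.0) ** 0.4
        for rep in range(3):
            radii = [base * f for f in (0.7, 1.0, 1.3, 0.9, 1.1)]
            spec = synthetic.SyntheticDropletSpec(
                image_shape=(256, 256), radii=radii, centers=layouts,
                noise_sigma=0.02, seed=SEED + 100 * rep + int(conc),
            )
            img, t = synthetic.gen_droplet_image(spec)
            io.write_tiff(OUT / f"droplets_c{conc:g}_r{rep}.tif", img)
            io.write_json(OUT / f"droplets_c{conc:g}_r{rep}_truth.json",
                          {"radii": t["radii"], "centers": t["centers"],
                           "conc_uM": conc})

    # FRAP movies: line bleach and whole-droplet bleach
    centers8 = [(20, 20), (20, 100), (60, 40), (60, 110),
                (100, 20), (100, 90), (40, 70), (90, 60)]
    line = synthetic.SyntheticFrapSpec(
        n_frames=80, image_shape=(128, 128), radii=[8] * 8, centers=centers8,
        decay=synthetic.SpatialDecayTruth(k1_0=0.05, k2_0=0.005),
        bleach_frame=10, bleach_roi=(18, 0, 21, 128),
        recovery_a=0.7, recovery_b=0.1, recovery_k1=0.35, recovery_k2=0.05,
        noise_sigma=0.5, seed=SEED,
    )
    movie, t = synthetic.gen_frap_movie(line)
    io.write_tiff(OUT / "frap_line.tif", movie)
    io.write_json(OUT / "frap_line_truth.json",
                  {"t_half": t["t_half"], "bleach_frame": 10,
                   "roi": [18, 0, 21, 128]})

    # unbleached references sit near the field edges, outside the
    # bleach-strike exclusion zone around the central target droplet
    centers_far = [(15, 15), (15, 64), (15, 110), (64, 15),
                   (64, 113), (110, 15), (110, 64), (112, 112)]
    whole = synthetic.SyntheticFrapSpec(
        n_frames=120, image_shape=(128, 128), radii=[8] * 9,
        centers=centers_far + [(64, 64)],
        decay=synthetic.SpatialDecayTruth(
            k1_0=0.05, alpha1=5e-4, beta1=2e-4, k2_0=0.005),
        bleach_frame=10, bleach_roi=(54, 54, 75, 75),
        recovery_a=0.8, recovery_b=0.1, recovery_k1=0.4, recovery_k2=0.05,
        noise_sigma=0.5, seed=SEED,
    )
    movie, t = synthetic.gen_frap_movie(whole)
    io.write_tiff(OUT / "frap_whole.tif", movie)
    io.write_json(OUT / "frap_whole_truth.json",
                  {"t_half": t["t_half"], "bleach_frame": 10,
                   "roi": [54, 54, 75, 75],
                   "decay": whole.decay})

    # optical-trap force-extension pair, 5 kbp sequestered
    fspec = synthetic.SyntheticForceExtensionSpec(
        compacted_bp=5000, noise_sigma=0.2, n_points=2000, seed=SEED,
    )
    bare, hp1, t = synthetic.gen_force_extension(fspec)
    io.write_force_curve(OUT / "force_bare.csv", bare)
    io.write_force_curve(OUT / "force_hp1.csv", hp1)
    io.write_json(OUT / "force_truth.json",
                  {"area_pN_um": t["area_pN_um"],
                   "compacted_bp": t["compacted_bp"],
                   "total_bp": t["total_bp"]})

    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main()
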