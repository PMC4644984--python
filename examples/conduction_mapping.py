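"""Activation map, isochrones and conduction velocity of a planar wave.

A noisy (snr 10) planar wave with a true CV of 19.1 cm/s is mapped by
maximum-rise activation detection; CV is estimated by regressing activation
time on distance along three automatic straight paths.
"""

from opticard import mapping, preprocess, synthetic

gt = synthetic.WaveGroundTruth(cv=19.1, duration80=260.0, n_beats=4,
                               snr=10.0, seed=1)
shape = (synthetic.n_frames_for(gt, (40, 120), 10 / 3, 0.05), 40, 120)
movie, _ = synthetic.gen_voltage_movie(gt, shape)

pre = preprocess.preprocess(movie)
res = mapping.activation_map(pre, beat_window=(0.0, 450.0))
res = mapping.conduction_velocity(res)
iso = mapping.isochrones(res, interval=10.0)

print(f"true CV: {gt.cv} cm/s")
print(res.cv_paths[["path", "n_points", "cv_cm_per_s", "valid"]].round(2).to_string(index=False))
print(f"mean CV over valid paths: {res.cv_mean:.2f} cm/s (should be within 5%)")
print(f"isochrone levels (10 ms spacing): {len(iso)}; for a planar wave these "
      "are parallel lines 1 pixel-row of ~0.96 mm apart at 19.1 cm/s")
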