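"""Quality control, gap interpolation and pose normalization.

Corrupts a clean synthetic session with a batch offset, dropouts and
outlier frames, then runs the preprocessing chain: QC (cage bounds +
collapse detection), piecewise-cubic gap filling, and per-frame
translate/scale/rotate normalization to the canonical torso frame.
"""

import numpy as np

from ethokit import (
    corrupt_session,
    default_skeleton,
    generate_markov_labels,
    interpolate_gaps,
    make_repertoire,
    normalize_pose,
    qc_filter,
    render_poses,
)

skeleton = default_skeleton()
rep = make_repertoire(seed=0)
labels, _ = generate_markov_labels(rep, 4000, seed=1)
clean = render_poses(labels, skeleton, rep, noise_sd=0.01, seed=2)

dirty = corrupt_session(
    clean,
    offset=np.array([0.02, -0.01, 0.005]),        # day-to-day batch shift
    dropout_runs=[(500, 6), (1200, 14)],          # tracking dropouts
    outlier_frames=[900, (1500, "collapse")],     # reconstruction failures
)

qc, report = qc_filter(dirty, skeleton)
print(f"QC: {report.n_out_of_bounds} out-of-cage, {report.n_collapsed} collapsed, "
      f"{100 * report.fraction_removed:.2f}% of frames removed")

filled = interpolate_gaps(qc, max_gap_frames=10)
n_recovered = filled.valid_mask.sum() - qc.valid_mask.sum()
print(f"interpolation recovered {n_recovered} frames "
      "(gaps <= 10 frames / 0.33 s are filled; the 14-frame gap is not)")

norm = normalize_pose(filled, skeleton)
neck, hip = skeleton.spine_pair
t = np.flatnonzero(norm.valid_mask)[0]
print(f"normalized frame {t}: neck at {norm.coords[t, neck].round(9)}, "
      f"spine length {np.linalg.norm(norm.coords[t, hip]):.9f}")
# After normalization every valid pose is dimensionless: neck at the
# origin, unit spine pointing down -Z, torso facing +X.
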