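# Example run configuration for `whiskertrack run -c config.yaml`.
# Angles are given in degrees in *_deg keys and converted on load.

video: scene/video.tif          # multi-page TIFF or a directory of frames
output_dir: out
fps: 1000
seed: 0

snout:
  p0: [20, 430]                 # two points (x, y) along the snout edge
  p1: [500, 430]
  flip_normal: false            # set true if whiskers lie on the other side

background:
  n_samples: 20                 # frames sampled for the per-pixel maximum

silhouette:
  threshold: null               # null -> Otsu on the subtracted frame
  open_radius: 3                # deletes whisker-width structures
  dilate_radius: 3              # pads the snout blob

preprocess:
  invert: false                 # true if whiskers are bright on dark
  side_margin: 8.0              # px above the snout line excluded from detection

detection:
  sigma: 1.5                    # Gaussian-derivative scale (px)
  min_strength: 4.0             # null -> 99th-percentile calibration
  min_theta_deg: 10             # reject near-snout-parallel clusters

cluster:
  method: steger                # or dbscan for rough/interrupted centerlines
  dbscan_eps: 2.5
  dbscan_min_pts: 3
  steger_angle_tol_deg: 30
  stitch_fit_len: 20
  stitch_max_dist: 3
  stitch_max_gap: 30
  min_whisker_len: 40
  snout_attach_dist: 10

fit:
  max_iter: 100
  tol: 1.0e-10

track:
  bootstrap_len: 50             # Kalman-only frames that seed the recogniser
  retrain_every: 25             # SVM retrain cadence (frames)
  window: 2000                  # training window W (frames)
  assign_max_cost: 3.0
  max_dtheta_deg: 10            # N-expert per-frame angle limit
  max_drho: 15                  # N-expert per-frame position limit (px)
  max_coast: 100

recognize:
  svm_c: 1.0
  min_train_samples: 20
  min_pivot_samples: 50
  min_theta_range_deg: 10
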