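# Example configuration for `mosaic build --config ...`.
# Only the keys you want to change need to appear; everything else
# keeps the defaults defined in endomosaic/config.py.

seed: 0
sources: [feature, flow, direct]
fusion_mode: graph          # graph | average | single:feature | single:flow | single:direct

estimation:
  eps: 2.0                  # RANSAC inlier threshold, px
  max_iters: 1000
  min_inliers: 10

flow:
  backend: ilk              # ilk | tvl1 | precomputed
  stride: 8                 # flow-field subsampling before RANSAC
  border_margin: 4

direct:
  pyramid_levels: 3
  max_iters: 50

uncertainty:
  min_inliers: 10
  max_residual: 0.01        # mean-squared intensity on the [0, 1] scale

loop_closure:
  enabled: true
  sim_thresh: 0.75          # bag-of-words cosine similarity
  min_gap: 20               # frames

graph:
  lambda0: 1.0e-4
  max_iters: 100
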