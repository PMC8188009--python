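Usage: main ef [OPTIONS]

  Compute the per-voxel ellipsoid factor of a binary (or thresholded) stack.

Options:
  --input PATH                    [required]
  --output-dir DIRECTORY          [required]
  --threshold FLOAT               Grayscale threshold (strict >); omit for
                                  already-binary input.
  --median-radius INTEGER         Radius of the 3D median denoising filter (0 =
                                  off).  [default: 0]
  --number-of-sampling-vectors INTEGER
                                  [default: 100]
  --sampling-increment FLOAT      [default: 0.4347826086956522]
  --skeleton-points-per-ellipsoid INTEGER
                                  [default: 10]
  --contact-sensitivity INTEGER   [default: 1]
  --maximum-iterations INTEGER    [default: 50]
  --maximum-drift FLOAT           Maximum seed drift in voxels (default: unit
                                  pixel diagonal).  [default:
                                  1.7320508075688772]
  --repetitions INTEGER           [default: 1]
  --average-over-largest-n INTEGER
                                  [default: 1]
  --seed-distance-ridge / --no-seed-distance-ridge
                                  [default: seed-distance-ridge]
  --seed-topology / --no-seed-topology
                                  [default: no-seed-topology]
  --show-secondary-images
  --show-convergence
  --production                    Preset for final results: skeleton points per
                                  ellipsoid 1, repetitions 6.
  --rng-seed INTEGER              [default: 0]
  --config PATH                   key = value configuration file; command-line
                                  flags override it.
  --help                          Show this message and exit.
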