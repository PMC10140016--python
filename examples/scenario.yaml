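# Demo scenario: 8-channel fractionated-dipole baseline array at 7.0 T on
# the small 24^3 torso phantom.  Run with:  ptxbench run examples/scenario.yaml
name: fd-bl7t
building_block: FD
setup: BL-7T
phantom: demo
array_scale: 0.6
seed: 1
mode: phase-amplitude
ga_population: 60
ga_generations: 20
kt_points: [4]
kt_candidates_per_axis: 3
gfactor_r: [2, 3, 4]
gfactor_axes: [y, x]
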