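# lipokin configuration template.
# Keys mirror the CarrierEnsemble / RateSet field names; units are explicit.
# Any key you omit falls back to the default shown by `lipokin simulate --show-config`.

n_donor: 100        # number of donor carriers N_d
n_acceptor: 100     # number of acceptor carriers N_a
volume: 1.0         # aqueous volume V (arbitrary volume units; k_coll and
                    # the uptake rates must use the same volume unit)
capacity: 100       # max drug molecules per carrier, m
k_offset: 0.0       # equilibrium per-carrier offset k, in drug molecules;
                    # must be an integer for distribution-level (master) runs
total_drug: 200.0   # total drug load M (initially all in the donors)

rates:
  k_coll: 0.0          # collision transfer rate, volume/time
  k_diff: 1.0          # diffusion transfer rate, 1/time
  k_rel_donor: 0.0     # donor release rate K_d^rel, 1/time
  k_rel_acceptor: 0.0  # acceptor release rate K_a^rel, 1/time
  k_upt_donor: 0.0     # donor uptake rate K_d^upt, volume/time
  k_upt_acceptor: 0.0  # acceptor uptake rate K_a^upt, volume/time
  flip_symmetric: null # symmetric flip-flop rate G, 1/time (overrides the
                       # four direction-resolved flip rates when set)

simulation:
  model: mono       # mono | high_loading | two_state | master_collision | master_diffusion
  kernel: ideal     # ideal | crowded   (master_collision only)
  donor_load: 2     # initial drug molecules per donor (master runs)
  acceptor_load: 0  # initial drug molecules per acceptor (master runs)
  t_max: 10.0       # end of the time grid, in 1/rate units
  n_points: 200     # output grid size
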