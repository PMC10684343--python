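# Synthetic example of an EB-microtubule rate parameter set (tip frame).
#
# These values are a constructed, order-of-magnitude-realistic stand-in
# assembled from the published kinetics of end-binding proteins (comet
# lengths of order 100 nm, single-EB dwell times of tens to hundreds of
# milliseconds that are several-fold longer in the tip region than on the
# GDP lattice, and in-vitro microtubule growth speeds of tens of nm/s).
# They are NOT a transcription of any specific measured data set; replace
# this file with measured rates for quantitative work.
#
# Units: rates in 1/s, lengths in nm, velocities in nm/s.

kappa1_tip: 50.0        # leg binding rate in the tip region
kappa1_lattice: 5.0     # leg binding rate on the mature lattice
kappa2_tip: 10.0        # leg unbinding rate in the tip region
kappa2_lattice: 50.0    # leg unbinding rate on the mature lattice
comet_length: 100.0     # exponential decay length of the comet behind the tip
x_edge: 0.0             # tip position in the co-moving frame
lattice_extent: 4000.0  # modelled lattice length behind the tip
v_MT: 50.0              # microtubule growth speed
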