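species_id	property	value	uncertainty	T_ref	source
formaldehyde_pool	formation_gibbs	125.3400	5.00	298.15	calorimetric_A
formaldehyde_pool	formation_gibbs	136.7486	6.50	298.15	equilibrium_B
formaldehyde_pool	formation_gibbs	132.3868	5.50	298.15	electrochemical_C
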