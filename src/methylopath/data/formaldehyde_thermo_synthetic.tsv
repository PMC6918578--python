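species_id	property	value	uncertainty	T_ref	source
methanol	formation_gibbs	128.8227	0.50	298.15	consistent_set
methanol	formation_enthalpy	-50.0000	1.00	298.15	consistent_set
methanol	heat_capacity	80.0	2.0	298.15	consistent_set
formaldehyde	formation_gibbs	149.3825	4.00	298.15	consistent_set
formaldehyde	formation_enthalpy	77.0056	2.00	298.15	consistent_set
formaldehyde	heat_capacity	80.0	2.0	298.15	consistent_set
methylene_glycol	formation_gibbs	130.5412	3.30	298.15	consistent_set
methylene_glycol	formation_enthalpy	41.0056	2.00	298.15	consistent_set
methylene_glycol	heat_capacity	80.0	2.0	298.15	consistent_set
nad_ox	formation_gibbs	0.0000	0.10	298.15	couple_anchor
nad_ox	formation_enthalpy	0.0000	0.10	298.15	couple_anchor
nad_ox	heat_capacity	0.0	0.0	298.15	couple_anchor
nad_red	formation_gibbs	22.6500	0.10	298.15	couple_anchor
nad_red	formation_enthalpy	-31.9400	0.10	298.15	couple_anchor
nad_red	heat_capacity	0.0	0.0	298.15	couple_anchor
formaldehyde_pool	formation_gibbs	130.5400	3.30	298.15	reconciled_reference
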