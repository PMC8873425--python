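# Example configuration for a field trial export (long-format CSV with
# columns population,genotype,plant,row,col,time,value,lot).
# Trait windows bracket the growth-rate maxima of interest: early stem
# elongation, recovery after a cold spell, and the pre-plateau phase
# (times in day-of-year units; adapt to the experiment at hand).
factors:
  lot: average
spatial:
  nested: true
hierarchical:
  b_pop: 20
  b_gen: 20
  b_plant: 20
  per_population_genetic: true
traits:
  windows:
    - [85.0, 110.0]
    - [120.0, 140.0]
    - [140.0, 160.0]
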