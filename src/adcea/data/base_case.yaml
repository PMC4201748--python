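# Base-case parameterization: two-arm Markov cohort model of nursing-home
# admission in Alzheimer's disease (community / institution / dead, 1-year
# cycles, 7-year horizon).  All monetary values in 2010 euros per year.
#
# The 2005->2010 consumer-price inflation factor implied by the nursing-home
# cost pair (28,843 / 26,301 = 1.09665) was already applied to the care costs
# below; medication costs are 2010 tariffs and were never inflated.
horizon_cycles: 7
cycle_length_years: 1.0
strategies:
  - name: "ChEI alone"
    p_institutionalisation: [0.0167, 0.1031, 0.0947, 0.0808, 0.0891, 0.0, 0.0]
    annual_medication_cost: 855.0
  - name: "ChEI + memantine"
    p_institutionalisation: [0.0, 0.0, 0.0, 0.0167, 0.0418, 0.0, 0.0]
    annual_medication_cost: 2013.0   # 855 (ChEI) + 1,158 (memantine)
mortality:
  p_death: [0.0300, 0.0335, 0.0375, 0.0421, 0.0475, 0.0539, 0.0612]
costs:
  community_direct_other: 13625.0    # direct community care excl. medication
  community_indirect: 5132.0         # informal help (societal perspective only)
  institution_direct_other: 28843.0  # nursing-home care excl. medication
  reference_year: 2010
utilities:
  u_community: 0.60
  u_institution: 0.34
discount:
  rate: 0.03
  half_cycle_correction: true
wtp_thresholds: [23065.0, 34598.0]
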