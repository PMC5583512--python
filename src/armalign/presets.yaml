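# Preset catalogue: genome geometry, inversion endpoints and simulation
# scenarios.  Lengths/positions in bp unless suffixed _kb.
genomes:
  caulobacter:
    # C. crescentus NA1000 chromosome geometry; ori defines coordinate 0,
    # parS ~8 kb counter-clockwise of ori (left arm), ter at the antipode.
    length_bp: 4042929
    ori_bp: 0
    parS_bp: 4034929
    ter_bp: 2021464

# Inversion endpoints on the left arm (kb values reported for the strains;
# endpoint 3 is not printed anywhere and is deliberately absent).
inversion_endpoints_bp:
  "1": 4038000
  "2": 4030000
  "4": 3788000
  "5": 3611000

inversions:
  flip15: {start: "5", end: "1"}
  flip25: {start: "5", end: "2"}
  flip24: {start: "4", end: "2"}
  flip45: {start: "5", end: "4"}

# Simulation scenarios.  Omitted keys fall back to SimConfig defaults
# (alpha=1.0, s0_kb=10, epsilon=3e-3, amplitude=0.04, sigma_kb=30,
# lam_kb=600, v_left=19, v_right=16, steady state).
scenarios:
  wt: {}
  dsmc:
    amplitude: 0.0
  flip25:
    # head-on rRNA/operon cluster reoriented close to parS: stall barrier on
    # the left arm; reduced processivity
    lam_kb: 420
    barriers:
      - {arm: left, offset_kb: 70, strength: 0.9, mode: stall}
  rif:
    # transcription inhibited: same strain, barriers off
    lam_kb: 420
    barriers: []
  flip24:
    lam_kb: 500
    barriers:
      - {arm: left, offset_kb: 80, strength: 0.6, mode: stall}
  flip45:
    # inverted segment starts ~290 kb from parS: two-phase pattern
    lam_kb: 600
    barriers:
      - {arm: left, offset_kb: 290, strength: 0.8, mode: stall}
  flip15:
    # parS relocated by the 5->1 inversion; reduced alignment extent
    parS_bp: 3614070
    lam_kb: 380
  ectopic_parS:
    # extra parS inserted at +1,800 kb; band re-centred there
    parS_bp: 1800000
    lam_kb: 300
  timecourse:
    # loader re-induction dynamics; finite t set per time point
    v_left: 19.0
    v_right: 16.0
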