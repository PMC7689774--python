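# Acquisition protocols.  Breath-hold and continuous-70 TRs are derived from
# the fixed scan time via TR = scan_time/(n_lines*NSA); printed TRs (20/12.5 ms)
# agree to rounding.  Full-recovery protocols use the printed TR/NSA directly.
# bw is Hz/pixel for imaging, total Hz for spectroscopy.
breath-hold-ofcb:
  tr_ms: 21.484375
  te_ms: 0.63
  flip_deg: 70
  nsa: 16
  n_lines: 32
  scan_time_s: 11
  matrix: [32, 32]
  fov_mm: [100, 100]
  bw: 436
breath-hold-pfp:
  tr_ms: 14.322916666666666
  te_ms: 0.63
  flip_deg: 70
  nsa: 24
  n_lines: 32
  scan_time_s: 11
  matrix: [32, 32]
  fov_mm: [100, 100]
  bw: 436
continuous-70-ofcb:
  tr_ms: 20.073784722222222
  te_ms: 0.95
  flip_deg: 70
  nsa: 144
  n_lines: 64
  scan_time_s: 185
  matrix: [64, 64]
  fov_mm: [100, 100]
  bw: 246
continuous-70-pfp:
  tr_ms: 13.079751131221719
  te_ms: 0.95
  flip_deg: 70
  nsa: 221
  n_lines: 64
  scan_time_s: 185
  matrix: [64, 64]
  fov_mm: [100, 100]
  bw: 246
full-recovery-ofcb:
  tr_ms: 100
  te_ms: 0.95
  flip_deg: 90
  nsa: 29
  n_lines: 64
  matrix: [64, 64]
  fov_mm: [100, 100]
  bw: 246
full-recovery-pfp:
  tr_ms: 63
  te_ms: 0.95
  flip_deg: 90
  nsa: 41
  n_lines: 64
  matrix: [64, 64]
  fov_mm: [100, 100]
  bw: 246
phantom-pure:
  tr_ms: 200
  te_ms: 1.0
  flip_deg: 90
  nsa: 1
  matrix: [64, 64]
  fov_mm: [100, 100]
phantom-mixture-ofcb:
  tr_ms: 100
  te_ms: 1.0
  flip_deg: 90
  nsa: 1
  matrix: [64, 64]
  fov_mm: [100, 100]
phantom-mixture-pfp:
  tr_ms: 63
  te_ms: 1.0
  flip_deg: 90
  nsa: 1
  matrix: [64, 64]
  fov_mm: [100, 100]
spectroscopy:
  tr_ms: 750
  te_ms: 0.14
  flip_deg: 90
  nsa: 1
  bw: 32000
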