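# Relaxation constants of the studied gases, one entry per condition.
# t1_ms / t2star_ms are the measured values (main peak); n_equivalent_f is the
# fluorine count of the imaged peak; peaks lists every resonance as
# [relative_area, offset_hz, t2star_ms].  The PFP CF3/CF2 separation defaults
# to 45 ppm at 120.15 MHz (~5407 Hz); no measured shift is available.
ofcb-pure:
  n_equivalent_f: 8
  t1_ms: 28.5
  t2star_ms: 10.5
  condition: pure
  peaks:
    - [8, 0.0, 10.5]
pfp-pure:
  n_equivalent_f: 6
  t1_ms: 18.6
  t2star_ms: 6.26
  condition: pure
  peaks:
    - [6, 0.0, 6.26]
    - [2, 5406.8, 6.26]
ofcb-o2:
  n_equivalent_f: 8
  t1_ms: 20.4
  t2star_ms: 8.6
  condition: O2-mixture
  peaks:
    - [8, 0.0, 8.6]
pfp-o2:
  n_equivalent_f: 6
  t1_ms: 14.98
  t2star_ms: 5.4
  condition: O2-mixture
  peaks:
    - [6, 0.0, 5.4]
    - [2, 5406.8, 5.4]
ofcb-invivo:
  n_equivalent_f: 8
  t1_ms: 17.77
  t2star_ms: 3.4
  condition: in-vivo
  peaks:
    - [8, 0.0, 3.4]
pfp-invivo:
  n_equivalent_f: 6
  t1_ms: 12.8
  t2star_ms: 2.2
  condition: in-vivo
  peaks:
    - [6, 0.0, 2.2]
    - [2, 5406.8, 2.2]
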