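# Reported SNR values from the original study, used by the report commands to
# redo the normalization arithmetic and to flag internal discrepancies.
# "source" records where in the study the number appears when two versions
# exist (summary-table vs narrative); none is chosen as canonical.
in_vivo:
  - gas: OFCB-O2
    protocol: breath-hold
    snr: 9.72
    snr_sd: 2.1
    nsa: 16
    reported_normalized: 0.61
    reported_normalized_sd: 0.13
    source: summary-table
  - gas: OFCB-O2
    protocol: breath-hold
    snr: 9.12
    snr_sd: 2.10
    nsa: 16
    reported_normalized: 0.61
    source: narrative
  - gas: OFCB-O2
    protocol: continuous-70
    snr: 14.48
    snr_sd: 4.51
    nsa: 144
    reported_normalized: 0.1
    reported_normalized_sd: 0.03
    source: summary-table
  - gas: OFCB-O2
    protocol: full-recovery
    snr: 10.23
    snr_sd: 0.70
    nsa: 29
    reported_normalized: 0.39
    reported_normalized_sd: 0.03
    source: summary-table
  - gas: PFP-O2
    protocol: breath-hold
    snr: 7.66
    snr_sd: 2.0
    nsa: 24
    reported_normalized: 0.32
    reported_normalized_sd: 0.08
    source: summary-table
  - gas: PFP-O2
    protocol: continuous-70
    snr: 12.68
    snr_sd: 4.09
    nsa: 221
    reported_normalized: 0.06
    reported_normalized_sd: 0.02
    source: summary-table
  - gas: PFP-O2
    protocol: full-recovery
    snr: 8.81
    snr_sd: 0.46
    nsa: 41
    reported_normalized: 0.21
    reported_normalized_sd: 0.01
    source: summary-table
phantom_gre:
  - {gas: OFCB, snr: 45.52, source: summary-table}
  - {gas: PFP, snr: 30.26, source: summary-table}
  - {gas: OFCB-O2, snr: 14.52, source: summary-table}
  - {gas: OFCB-O2, snr: 14.22, source: narrative}
  - {gas: PFP-O2, snr: 9.42, source: summary-table}
phantom_spectroscopy:
  - {gas: OFCB, snr: 628.44}
  - {gas: OFCB-O2, snr: 499.91}
  - {gas: PFP, snr: 400.44}
  - {gas: PFP-O2, snr: 362.10}
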