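"""Event-related design: a single neural spike under acquisition noise.

Simulates one spike at t = 30 s in a 12x12x12 phantom at ~13 dB peak
SNR, regularizes with the default flow, and inspects the strongest
voxel's recovered series: where its peak lies relative to the true
spike, how salient the peak is above baseline, and how much smoother
the series is than the acquired data.
"""

from aniso4d.study import spike_recovery

res = spike_recovery(spike_time_s=30.0, psnr_target_db=13.0, seed=5)

print(f"realized pSNR            : {res['psnr_realized_db']:.2f} dB")
print(f"peak offset from spike   : {res['peak_offset_tr']:+d} TR")
print(f"peak height above median : {res['peak_robust_z']:.1f} robust SDs")
print(f"total variation          : recovered {res['tv_recovered']:.1f} "
      f"vs acquired {res['tv_raw']:.1f}")
print()
print("The peak is salient (well above the baseline) and the recovered")
print("series is smoother than the data, but the peak sits several TRs after")
print("the true spike: the hemodynamic response delays the BOLD peak and the")
print("flow's fidelity weight (1 - alpha = 3e-4) is far too small to undo")
print("that convolution within 40 iterations.")
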