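Limb,TL (mm),FL (mm),Flexion Angle (deg),QCA (cm^2),QCA.FL (cm^2.m),Moment Arm (mm),TT Projection Index,TP:TT Ratio,Pennation Angle VL (deg),Pennation Angle RF (deg)
Limb 1,395.5,196.1,78.2,77.1,15.1,29.1,15.3,1.4,32.1,45.8
Limb 2,392.9,189.9,70.0,81.6,15.4,28.6,18.2,1.9,19.0,20.8
Limb 3,418.9,205.2,68.4,101.7,20.9,28.5,17.8,1.7,24.8,29.3
Limb 4,405.3,209.2,88.6,86.1,18.0,32.2,18.0,1.8,29.9,27.9
Median,400.4,200.7,74.1,83.9,16.7,28.9,17.9,1.8,27.4,28.6
Range,26.0,19.3,20.2,24.6,5.8,3.7,2.9,0.5,13.1,25.0
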