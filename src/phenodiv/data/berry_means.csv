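# Published genotype-level means and standard errors (n = 3 replicates) for
# berries of 25 raspberry genotypes: total phenolics (TPC, mg GAE/100 g FW),
# total flavonoids (TFC, mg RE/100 g FW), monomeric anthocyanins (TAC,
# mg cyan-3-G/100 g FW), and antioxidant capacity by FRAP and ABTS
# (umol TE/g FW).
genotype,fruit_color,TPC,TPC_se,TFC,TFC_se,TAC,TAC_se,FRAP,FRAP_se,ABTS,ABTS_se
1-14-1,red,236.6,16.3,151.2,16.6,29.2,2.7,22.9,0.8,27.5,1.8
1-14-2,red,292.1,20.2,184.3,12.1,39.2,2.7,27.6,2.7,41.2,3.4
1-14-2(zh),yellow,267.4,27.9,159.3,18.9,0.5,0.1,23.0,1.6,33.6,1.6
1-45-1,red,305.5,32.5,206.3,25.7,30.2,1.1,30.3,2.4,44.6,4.6
1-45-2,red,349.5,31.2,261.1,24.4,40.2,5.0,35.9,3.7,52.4,5.4
1-70-1,red,304.2,14.3,235.5,8.6,64.9,5.9,33.5,1.8,35.7,1.6
2-66-1,red,287.0,11.1,194.4,8.3,39.9,4.9,26.1,1.2,34.4,1.4
2-66-2,red,315.7,40.8,210.4,21.4,35.7,4.8,34.0,4.5,41.1,5.1
2-66-3,red,224.6,3.6,119.8,11.0,31.0,4.8,22.8,0.9,33.5,0.5
3-117-1,red,224.4,12.3,149.7,10.8,30.1,0.9,20.9,1.3,26.0,1.4
9-121-2,red,189.0,14.1,123.7,8.8,20.9,1.8,14.1,1.2,22.7,1.3
9-121-4,red,215.4,4.1,124.4,3.4,30.3,4.2,23.1,1.1,30.6,1.2
9-121-5,yellow,315.9,16.1,212.3,11.8,1.1,0.1,25.3,1.5,41.2,1.5
11-110-2,red,255.4,20.9,173.8,14.2,35.0,3.8,26.5,1.8,38.2,2.7
Abrikosovaya,yellow-orange,225.6,10.7,118.1,7.1,0.7,0.1,22.4,1.5,34.8,2.0
Arbat,red,232.5,9.8,182.1,8.6,39.3,0.8,23.4,1.4,36.5,2.6
Gusar,red,289.6,8.5,189.6,9.1,28.3,1.0,27.9,1.8,34.6,2.5
Karamelka,red,274.0,8.8,161.7,4.3,22.4,3.0,28.1,0.7,42.0,1.3
Himbo Top,red,227.4,21.6,166.1,9.4,31.4,2.7,22.5,2.2,26.9,2.9
Octavia,red,307.8,15.7,182.7,7.0,16.4,1.6,27.2,1.2,36.7,1.2
Polana,red,224.2,4.0,166.1,14.2,31.2,1.5,23.9,0.6,24.9,0.7
Polesie,red,273.9,4.4,187.7,6.3,37.3,0.7,25.5,0.5,33.2,1.6
Polka,red,240.2,9.4,163.5,3.6,34.8,1.1,22.5,0.6,28.4,0.8
Porana Rosa,yellow,148.4,6.0,100.5,5.9,0.3,0.1,11.7,0.6,19.2,0.5
Silvan,black,352.7,17.1,313.7,17.2,89.8,2.4,38.3,1.4,47.6,2.7
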