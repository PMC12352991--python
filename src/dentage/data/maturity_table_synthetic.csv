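# SYNTHETIC maturity table for tests and demonstration only.
# Not a published dental-maturity standard; scores are self-weighted so the
# all-H total is 100, and the conversion knots invert the simulator's
# synthetic staging thresholds. Supply a real population standard for use.
sex,tooth_fdi,stage,score,maturity_score,dental_age
F,31,UNFORMED,0.0,,
F,31,A,0.8,,
F,31,B,1.9,,
F,31,C,3.2,,
F,31,D,5.0,,
F,31,E,7.0,,
F,31,F,9.2,,
F,31,G,11.5,,
F,31,H,13.5,,
F,32,UNFORMED,0.0,,
F,32,A,0.8,,
F,32,B,1.9,,
F,32,C,3.3,,
F,32,D,5.1,,
F,32,E,7.2,,
F,32,F,9.5,,
F,32,G,11.8,,
F,32,H,13.9,,
F,33,UNFORMED,0.0,,
F,33,A,0.8,,
F,33,B,2.0,,
F,33,C,3.4,,
F,33,D,5.2,,
F,33,E,7.3,,
F,33,F,9.6,,
F,33,G,12.0,,
F,33,H,14.1,,
F,34,UNFORMED,0.0,,
F,34,A,0.9,,
F,34,B,2.0,,
F,34,C,3.4,,
F,34,D,5.3,,
F,34,E,7.4,,
F,34,F,9.7,,
F,34,G,12.2,,
F,34,H,14.3,,
F,35,UNFORMED,0.0,,
F,35,A,0.9,,
F,35,B,2.0,,
F,35,C,3.5,,
F,35,D,5.4,,
F,35,E,7.5,,
F,35,F,9.9,,
F,35,G,12.3,,
F,35,H,14.5,,
F,36,UNFORMED,0.0,,
F,36,A,0.9,,
F,36,B,2.1,,
F,36,C,3.5,,
F,36,D,5.4,,
F,36,E,7.6,,
F,36,F,10.0,,
F,36,G,12.5,,
F,36,H,14.7,,
F,37,UNFORMED,0.0,,
F,37,A,0.9,,
F,37,B,2.1,,
F,37,C,3.6,,
F,37,D,5.5,,
F,37,E,7.8,,
F,37,F,10.2,,
F,37,G,12.8,,
F,37,H,15.0,,
F,,,,0,2.0
F,,,,8.6,3.0
F,,,,24.6,5.0
F,,,,43.2,7.0
F,,,,63.7,9.0
F,,,,74.4,10.0
F,,,,84.0,11.0
F,,,,88.8,12.0
F,,,,95.6,13.0
F,,,,97.8,14.0
F,,,,100,15.5
M,31,UNFORMED,0.0,,
M,31,A,0.9,,
M,31,B,2.0,,
M,31,C,3.5,,
M,31,D,5.3,,
M,31,E,7.3,,
M,31,F,9.4,,
M,31,G,11.6,,
M,31,H,13.5,,
M,32,UNFORMED,0.0,,
M,32,A,1.0,,
M,32,B,2.1,,
M,32,C,3.6,,
M,32,D,5.4,,
M,32,E,7.5,,
M,32,F,9.7,,
M,32,G,12.0,,
M,32,H,13.9,,
M,33,UNFORMED,0.0,,
M,33,A,1.0,,
M,33,B,2.1,,
M,33,C,3.7,,
M,33,D,5.5,,
M,33,E,7.6,,
M,33,F,9.9,,
M,33,G,12.1,,
M,33,H,14.1,,
M,34,UNFORMED,0.0,,
M,34,A,1.0,,
M,34,B,2.1,,
M,34,C,3.7,,
M,34,D,5.6,,
M,34,E,7.7,,
M,34,F,10.0,,
M,34,G,12.3,,
M,34,H,14.3,,
M,35,UNFORMED,0.0,,
M,35,A,1.0,,
M,35,B,2.2,,
M,35,C,3.8,,
M,35,D,5.7,,
M,35,E,7.8,,
M,35,F,10.1,,
M,35,G,12.5,,
M,35,H,14.5,,
M,36,UNFORMED,0.0,,
M,36,A,1.0,,
M,36,B,2.2,,
M,36,C,3.8,,
M,36,D,5.7,,
M,36,E,7.9,,
M,36,F,10.3,,
M,36,G,12.6,,
M,36,H,14.7,,
M,37,UNFORMED,0.0,,
M,37,A,1.1,,
M,37,B,2.2,,
M,37,C,3.9,,
M,37,D,5.9,,
M,37,E,8.1,,
M,37,F,10.5,,
M,37,G,12.9,,
M,37,H,15.0,,
M,,,,0,2.0
M,,,,7.8,3.0
M,,,,23.6,5.0
M,,,,42.3,7.0
M,,,,63.0,9.0
M,,,,75.7,10.0
M,,,,84.7,11.25
M,,,,89.5,12.0
M,,,,95.9,13.25
M,,,,97.9,14.25
M,,,,100,15.5
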