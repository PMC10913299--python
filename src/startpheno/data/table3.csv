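measure,group,n,mean,sd
social_preference,TD,40,0.59,0.09
social_preference,AS,40,0.52,0.12
social_preference,ID,38,0.53,0.09
social_choice,TD,39,0.47,0.24
social_choice,AS,27,0.52,0.28
social_choice,ID,38,0.52,0.21
wheel_looking,TD,37,0.46,0.37
wheel_looking,AS,41,0.73,0.33
wheel_looking,ID,39,0.66,0.36
motor_rmse,TD,40,203.80,97.95
motor_rmse,AS,40,591.27,283.63
motor_rmse,ID,35,404.70,216.74
fft_gain_x,TD,40,1.53,0.40
fft_gain_x,AS,36,2.01,0.76
fft_gain_x,ID,34,2.02,0.72
fft_gain_y,TD,40,10.33,9.12
fft_gain_y,AS,36,25.28,15.42
fft_gain_y,ID,34,20.27,11.51
jerk,TD,40,0.06,0.13
jerk,AS,40,0.05,0.13
jerk,ID,35,0.05,0.13
pop_force,TD,40,0.07,0.01
pop_force,AS,41,0.09,0.02
pop_force,ID,39,0.08,0.02
pop_dist_x,TD,40,45.20,11.78
pop_dist_x,AS,41,88.97,57.34
pop_dist_x,ID,39,66.81,22.49
pop_dist_y,TD,40,54.95,13.59
pop_dist_y,AS,41,87.02,43.17
pop_dist_y,ID,39,75.01,25.03
colour_crossings,TD,37,23.05,16.98
colour_crossings,AS,29,56.40,29.43
colour_crossings,ID,27,49.81,28.31
pci_caregiver_sync,TD,32,0.33,0.22
pci_caregiver_sync,AS,35,0.15,0.11
pci_caregiver_sync,ID,33,0.20,0.14
pci_child_init,TD,32,0.48,0.24
pci_child_init,AS,35,0.23,0.24
pci_child_init,ID,33,0.40,0.23
questionnaire_score,TD,40,1.03,1.31
questionnaire_score,AS,48,5.06,2.26
questionnaire_score,ID,43,3.09,2.32
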