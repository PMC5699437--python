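country,sd,sd_se,fd,fd_se,pd,pd_se
Austria,92,0.03,94.2,0.01,92.6,0.01
Belgium,87.4,0.04,92.6,0.01,90.4,0.01
Bulgaria,88.2,0.02,93.8,0.01,91.6,0.01
Cyprus,87.6,0.06,93.1,0.03,91,0.02
Czech Republic,86.5,0.03,92.8,0.01,90.8,0.01
Hungary,82,0.03,92,0.01,89.7,0.01
Lithuania,88.5,0.02,93.8,0.01,91.6,0.01
Latvia,90.7,0.02,94.5,0.01,92.9,0.01
Luxembourg,89.9,0.11,93.6,0.03,91.4,0.03
Netherlands,85.1,0.04,91.8,0.01,89.6,0.01
Poland,84.2,0.02,92.4,0,90.3,0
Malta,91.4,0.18,95.2,0.12,91.7,0.07
Romania,89.7,0.01,94.2,0,91.9,0
Slovakia,88.7,0.04,93.4,0.01,91.6,0.01
Slovenia,93.2,0.05,94.7,0.02,93.2,0.02
Germany,86.3,0.01,92.2,0,90.2,0
Denmark,79.7,0.04,90.7,0.01,88.9,0.01
Estonia,91.5,0.02,94.5,0.01,93.1,0.01
Spain,85.9,0.01,93.3,0,91.2,0
Finland,98.6,0.01,98,0,97.4,0
France,86.7,0.01,92.9,0,91,0
United Kingdom,83.2,0.02,91.2,0.01,89.6,0
Greece,86.9,0.02,93.1,0.01,91.3,0.01
Ireland,80.5,0.02,89.8,0.01,88.5,0.01
Italy,87.5,0.01,93.1,0.01,91,0
Sweden,98.1,0.01,97.8,0,97.1,0
Portugal,90.7,0.02,93.9,0.01,92,0.01
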