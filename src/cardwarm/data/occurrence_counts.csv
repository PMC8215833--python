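feature,count
age,4
sex,20
cp,18
trestbps,4
chol,5
fbs,12
restecg,10
thalach,8
exang,12
oldpeak,14
slope,12
ca,19
thal,14
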