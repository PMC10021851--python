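state,mmr
Arunachal Pradesh,284
Manipur,282
Andaman and Nicobar Islands,275
Meghalaya,266
Sikkim,228
Assam,209
Uttar Pradesh,208
Lakshadweep,208
Madhya Pradesh,179
Bihar,164
Rajasthan,162
Delhi,162
Jammu and Kashmir,151
Chhattisgarh,144
Punjab,143
Nagaland,143
Odisha,138
Mizoram,131
Himachal Pradesh,127
Tripura,119
Uttarakhand,107
West Bengal,100
Goa,91
Haryana,90
Karnataka,85
Jharkhand,78
Gujarat,76
Andhra Pradesh,64
Dadra and Nagar Haveli,61
Tamil Nadu,56
Telangana,53
Daman and Diu,48
Kerala,44
Puducherry,41
Maharashtra,40
Chandigarh,15
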